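"""Synthetic cohorts with the statistical structure the analyses assume.

Three generators mirror the study design:

* :func:`simulate_proteomics` — a cross-sectional case–control cohort
  (cohort I, paired serum + CSF, 30 controls / 75 MS) measured on panel
  run 1, and a prospective MS cohort (cohort II, 93 patients, serum)
  measured on panel run 2, with 11 bridging samples re-measured on run 2.
  NPX values are Gaussian around protein baselines with subtype, age, sex,
  compartment and run-offset effects, censored below a per-protein LOD
  (emitted as below-LOD flags, forcing the imputation path).
* :func:`simulate_converter_trajectories` — longitudinal serum series for
  converters (default 12 x 7 visits) whose designated "granzyme-like"
  proteins follow a piecewise-linear tent peak anchored at conversion,
  plus flat non-converting RR patients with the same noise; a few "drift"
  proteins change in everyone (not conversion-specific).
* :func:`simulate_mirna_counts` — negative-binomial miRNA counts with
  log-normal library-size factors, per-miRNA batch/age/sex coefficients,
  subtype fold changes, and latent cell-type signature loadings; converter
  samples couple immune-cell loadings to the tent peak and a pericyte-like
  loading to its mirror image (a dip).

Every generator is deterministic in the config seed and returns a truth
table sufficient to score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import DAYS_PER_YEAR, NpxMatrix, CountMatrix, validate_meta

__all__ = [
    "SimConfig",
    "simulate_proteomics",
    "simulate_converter_trajectories",
    "simulate_mirna_counts",
]

_EPOCH = pd.Timestamp("2015-01-01")


@dataclass
class SimConfig:
    """Study-design and effect-size parameters for the generators.

    Defaults follow the study layout: cohort I with 30 controls and 75 MS
    patients (equal RR/SP/PP split), cohort II with 93 MS patients of whom
    38 are RR including 12 converters, 92-protein panel, NPX noise
    sigma = 0.5, tent peak amplitude 3*sigma over a 2-year half-width.
    """

    # cohort composition (individuals)
    cohort1: dict = field(default_factory=lambda: {"control": 30, "RR": 25, "SP": 25, "PP": 25})
    cohort2: dict = field(default_factory=lambda: {"control": 0, "RR": 26, "SP": 35, "PP": 20})
    n_converters: int = 12
    visits_per_converter: int = 7
    anchor_visit: int = 4          # 0-based index of the first SP visit
    visit_spacing_years: float = 0.5
    nonconverter_visits: int = 2
    nonconverter_span_years: float = 3.0

    # proteomics
    n_proteins: int = 92
    n_diff_proteins: int = 10
    protein_effect: float = 1.0    # NPX shift carried by differential proteins
    protein_sigma: float = 0.5     # NPX technical (measurement) SD
    bio_sigma: float = 1.0         # between-sample biological SD, shared across runs
    age_slope: float = 0.01        # NPX per year of age
    sex_effect: float = 0.1        # NPX shift for males
    compartment_shift: float = 1.0  # serum minus CSF baseline difference
    run_offset_max: float = 1.0    # run-2 offsets drawn U(-max, max)
    n_bridging: int = 11
    lod_quantile: float = 0.05

    # tent peak (longitudinal)
    n_peak_proteins: int = 3
    peak_amplitude: float = 1.5    # NPX, = 3*sigma at defaults
    peak_width_years: float = 2.0
    n_drift_proteins: int = 3
    drift_slope: float = -0.3      # NPX/year, present in everyone

    # miRNA counts
    n_mirnas: int = 180
    n_diff_mirnas: int = 20
    mirna_log2fc: float = 1.0
    nb_dispersion: float = 0.2
    baseline_mean: float = 100.0   # mean counts per miRNA before scaling
    libsize_log_sd: float = 0.4
    n_batches: int = 2
    batch_log2fc_sd: float = 0.3
    signature_strength: float = 1.0   # log2 loading of planted cell-type activity
    lambda_noise_sd: float = 0.1
    compartment_loading: float = 1.5  # CSF brain / serum immune baseline loading
    immune_celltypes: tuple = ("CD4_T", "CD8_T", "NK")
    brain_celltypes: tuple = ("neuron", "astrocyte")
    pericyte_celltype: str = "pericyte"

    seed: int = 0

    def validate(self) -> None:
        counts = list(self.cohort1.values()) + list(self.cohort2.values()) + [
            self.n_converters, self.visits_per_converter, self.n_proteins, self.n_mirnas,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("all cohort/feature counts must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be > 0")
        if not 0 < self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in (0, 1)")
        if not 0 < self.anchor_visit < self.visits_per_converter:
            raise ValueError("anchor visit must leave samples on both sides")


def _protein_ids(cfg: SimConfig) -> list[str]:
    return [f"P{i + 1:03d}" for i in range(cfg.n_proteins)]


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed, salt))


def tent(t: np.ndarray, width: float) -> np.ndarray:
    """Piecewise-linear peak profile (1 - |t|/w)+ anchored at t = 0."""
    return np.maximum(0.0, 1.0 - np.abs(np.asarray(t, dtype=float)) / width)


# ---------------------------------------------------------------------------
# cross-sectional proteomics
# ---------------------------------------------------------------------------

def _crosssec_individuals(cfg: SimConfig, rng) -> pd.DataFrame:
    rows = []
    for cohort, comp in (("I", cfg.cohort1), ("II", cfg.cohort2)):
        for subtype, n in comp.items():
            for _ in range(n):
                progressive = subtype in ("SP", "PP")
                age = float(np.clip(rng.normal(55 if progressive else 45, 10), 20, 85))
                rows.append({
                    "individual_id": f"ind{len(rows) + 1:04d}",
                    "cohort": cohort, "subtype": subtype, "age": age,
                    "sex": "M" if rng.random() < 0.5 else "F",
                })
    return pd.DataFrame(rows)


def simulate_proteomics(cfg: SimConfig):
    """Two-run cross-sectional NPX data with bridging samples.

    Returns ``(run1, run2, meta, truth)``. Run 1 holds cohort I (serum and
    paired CSF); run 2 holds cohort II serum plus the re-measured bridging
    samples (same individuals, fresh noise, run offsets applied). The truth
    table records each protein's MS effect, stage (SP/PP) effect and the
    run-2 offset; recovered bridging deltas estimate the negated offset.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    proteins = _protein_ids(cfg)
    inds = _crosssec_individuals(cfg, rng)

    mu = rng.normal(5.0, 1.0, cfg.n_proteins)
    diff = rng.choice(cfg.n_proteins, size=min(cfg.n_diff_proteins, cfg.n_proteins),
                      replace=False)
    ms_effect = np.zeros(cfg.n_proteins)
    stage_effect = np.zeros(cfg.n_proteins)
    half = len(diff) // 2
    ms_effect[diff[:half]] = cfg.protein_effect           # control vs MS
    stage_effect[diff[half:]] = cfg.protein_effect        # RR vs SP/PP
    run_offset = rng.uniform(-cfg.run_offset_max, cfg.run_offset_max, cfg.n_proteins)

    meta_rows, latent_rows, run_labels, sample_ids = [], [], [], []

    def latent(ind_row, compartment):
        subtype = ind_row["subtype"]
        x = mu.copy()
        if subtype != "control":
            x = x + ms_effect
        if subtype in ("SP", "PP"):
            x = x + stage_effect
        x = x + cfg.age_slope * (ind_row["age"] - 50.0)
        if ind_row["sex"] == "M":
            x = x + cfg.sex_effect
        if compartment == "CSF":
            x = x - cfg.compartment_shift
        # biological sample-level deviation: part of the aliquot, so shared
        # by any re-measurement of the same sample (bridging)
        return x + rng.normal(0.0, cfg.bio_sigma, cfg.n_proteins)

    day = 0
    for _, ind in inds.iterrows():
        compartments = ("serum", "CSF") if ind["cohort"] == "I" else ("serum",)
        date = (_EPOCH + pd.Timedelta(days=day)).strftime("%Y-%m-%d")
        day += 3
        for comp in compartments:
            sid = f"{ind['individual_id']}_{comp}"
            sample_ids.append(sid)
            run_labels.append("run1" if ind["cohort"] == "I" else "run2")
            latent_rows.append(latent(ind, comp))
            meta_rows.append({
                "sample_id": sid, "individual_id": ind["individual_id"],
                "cohort": ind["cohort"], "compartment": comp,
                "subtype": ind["subtype"], "age": ind["age"], "sex": ind["sex"],
                "sample_date": date, "converter": False, "conversion_date": None,
                "batch": f"b{1 + (len(meta_rows) % cfg.n_batches)}",
            })

    latent_mat = np.vstack(latent_rows)
    noise = rng.normal(0.0, cfg.protein_sigma, latent_mat.shape)
    values = latent_mat + noise
    run = pd.Series(run_labels, index=sample_ids)
    is_run2 = (run == "run2").to_numpy()
    values[is_run2] = values[is_run2] + run_offset

    # LOD from the marginal distribution of measured serum values
    total_sd = float(np.hypot(cfg.protein_sigma, cfg.bio_sigma))
    lod = mu + total_sd * sps.norm.ppf(cfg.lod_quantile)
    below = values < lod[None, :]
    vals_df = pd.DataFrame(np.where(below, np.nan, values), index=sample_ids,
                           columns=proteins)
    below_df = pd.DataFrame(below, index=sample_ids, columns=proteins)
    lod_s = pd.Series(lod, index=proteins)

    run1 = NpxMatrix(vals_df[~is_run2].copy(), lod_s.copy(), run[~is_run2].copy(),
                     below_df[~is_run2].copy())

    # run 2: cohort II serum + bridging re-measurements of cohort-I serum
    cohort1_serum = [s for s, r, m in zip(sample_ids, run_labels, meta_rows)
                     if r == "run1" and m["compartment"] == "serum"]
    bridging = list(rng.choice(cohort1_serum, size=cfg.n_bridging, replace=False))
    bridge_latent = latent_mat[[sample_ids.index(s) for s in bridging]]
    bridge_vals = (bridge_latent + rng.normal(0.0, cfg.protein_sigma, bridge_latent.shape)
                   + run_offset)
    bridge_below = bridge_vals < lod[None, :]
    run2_vals = pd.concat([
        vals_df[is_run2],
        pd.DataFrame(np.where(bridge_below, np.nan, bridge_vals), index=bridging,
                     columns=proteins),
    ])
    run2_below = pd.concat([
        below_df[is_run2],
        pd.DataFrame(bridge_below, index=bridging, columns=proteins),
    ])
    run2 = NpxMatrix(run2_vals, lod_s.copy(),
                     pd.Series("run2", index=run2_vals.index), run2_below)

    meta = validate_meta(pd.DataFrame(meta_rows))
    truth = pd.DataFrame({
        "protein_id": proteins, "ms_effect": ms_effect,
        "stage_effect": stage_effect, "run_offset": run_offset,
    })
    truth.attrs["bridging_ids"] = bridging
    return run1, run2, meta, truth


# ---------------------------------------------------------------------------
# longitudinal converter trajectories
# ---------------------------------------------------------------------------

def simulate_converter_trajectories(cfg: SimConfig):
    """Longitudinal serum NPX for converters and non-converting RR patients.

    Returns ``(npx, meta, truth)``. The first ``n_peak_proteins`` proteins
    carry the tent peak (amplitude ``peak_amplitude``, half-width
    ``peak_width_years``) in converters only; the next ``n_drift_proteins``
    drift linearly in everyone; the rest are flat. Visit ``anchor_visit``
    is the first SP-classified sample (t = 0).
    """
    cfg.validate()
    if cfg.n_converters < 1:
        raise ValueError("need at least one converter")
    rng = _rng(cfg, 2)
    proteins = _protein_ids(cfg)
    mu = rng.normal(5.0, 1.0, cfg.n_proteins)
    roles = np.array(["flat"] * cfg.n_proteins, dtype=object)
    roles[: cfg.n_peak_proteins] = "peak"
    roles[cfg.n_peak_proteins: cfg.n_peak_proteins + cfg.n_drift_proteins] = "drift"

    meta_rows, values, sample_ids = [], [], []
    day0 = 0

    def add_sample(ind, visit, date, t_years, subtype, converter, conv_date, age, sex):
        sid = f"{ind}_v{visit}"
        sample_ids.append(sid)
        meta_rows.append({
            "sample_id": sid, "individual_id": ind, "cohort": "II",
            "compartment": "serum", "subtype": subtype, "age": age, "sex": sex,
            "sample_date": date.strftime("%Y-%m-%d"), "converter": converter,
            "conversion_date": conv_date.strftime("%Y-%m-%d") if conv_date is not None else None,
            "batch": f"b{1 + len(meta_rows) % cfg.n_batches}",
        })
        level = mu.copy()
        for j in range(cfg.n_proteins):
            if roles[j] == "peak" and converter:
                level[j] += cfg.peak_amplitude * tent(np.array([t_years]),
                                                      cfg.peak_width_years)[0]
            elif roles[j] == "drift":
                level[j] += cfg.drift_slope * t_years
        values.append(level + rng.normal(0.0, cfg.protein_sigma, cfg.n_proteins))

    for i in range(cfg.n_converters):
        ind = f"conv{i + 1:03d}"
        age = float(np.clip(rng.normal(48, 8), 25, 75))
        sex = "M" if rng.random() < 0.5 else "F"
        start = _EPOCH + pd.Timedelta(days=day0)
        day0 += 11
        anchor_date = start + pd.Timedelta(
            days=round(cfg.anchor_visit * cfg.visit_spacing_years * DAYS_PER_YEAR))
        for v in range(cfg.visits_per_converter):
            date = start + pd.Timedelta(days=round(v * cfg.visit_spacing_years * DAYS_PER_YEAR))
            t_years = (date - anchor_date).days / DAYS_PER_YEAR
            subtype = "RR" if v < cfg.anchor_visit else "SP"
            add_sample(ind, v, date, t_years, subtype, True, anchor_date, age, sex)

    n_nonconv = cfg.cohort2["RR"] - cfg.n_converters
    for i in range(max(0, n_nonconv)):
        ind = f"nonc{i + 1:03d}"
        age = float(np.clip(rng.normal(48, 8), 25, 75))
        sex = "M" if rng.random() < 0.5 else "F"
        start = _EPOCH + pd.Timedelta(days=day0)
        day0 += 11
        span = cfg.nonconverter_span_years
        for v in range(cfg.nonconverter_visits):
            frac = v / max(1, cfg.nonconverter_visits - 1)
            date = start + pd.Timedelta(days=round(frac * span * DAYS_PER_YEAR))
            t_years = frac * span
            add_sample(ind, v, date, t_years, "RR", False, None, age, sex)

    vals_df = pd.DataFrame(np.vstack(values), index=sample_ids, columns=proteins)
    lod = pd.Series(vals_df.min().to_numpy() - 10.0, index=proteins)  # no censoring
    npx = NpxMatrix(vals_df, lod, pd.Series("long", index=vals_df.index))
    meta = validate_meta(pd.DataFrame(meta_rows))
    truth = pd.DataFrame({
        "protein_id": proteins, "role": roles,
        "amplitude": np.where(roles == "peak", cfg.peak_amplitude, 0.0),
        "width_years": np.where(roles == "peak", cfg.peak_width_years, np.nan),
        "drift_slope": np.where(roles == "drift", cfg.drift_slope, 0.0),
    })
    return npx, meta, truth


# ---------------------------------------------------------------------------
# miRNA counts
# ---------------------------------------------------------------------------

def simulate_mirna_counts(cfg: SimConfig, meta: pd.DataFrame,
                          signatures: dict[str, list[str]]):
    """NB miRNA counts for the samples in ``meta`` with planted structure.

    The measured panel is every signature miRNA plus background miRNAs up
    to ``n_mirnas``. Per-sample latent cell-type activities lambda (log2
    units) load the corresponding signature miRNAs: CSF samples carry
    brain-type loadings and serum samples a milder immune loading
    (compartment separation); converter samples add the tent peak to the
    immune types and its negation to the pericyte-like type. A subset of
    non-signature miRNAs carries a subtype (SP) fold change. Returns
    ``(counts, truth)`` with ``truth = {"mirna": per-miRNA table,
    "lambda": sample x cell-type activities}``.
    """
    cfg.validate()
    rng = _rng(cfg, 3)
    sig_mirnas = sorted({m for ids in signatures.values() for m in ids})
    if len(sig_mirnas) > cfg.n_mirnas:
        raise ValueError("n_mirnas smaller than the signature universe")
    background = [f"miR-bg{i + 1:03d}" for i in range(cfg.n_mirnas - len(sig_mirnas))]
    mirnas = sig_mirnas + background
    absent = [m for ids in signatures.values() for m in ids if m not in mirnas]
    if absent:
        raise ValueError("signature miRNA absent from panel: " + ", ".join(absent[:5]))

    meta = meta.reset_index(drop=True)
    n_s, n_m = len(meta), len(mirnas)
    celltypes = list(signatures)

    q = rng.lognormal(mean=np.log(cfg.baseline_mean), sigma=1.2, size=n_m)
    beta_batch = rng.normal(0.0, cfg.batch_log2fc_sd, n_m)
    beta_age = rng.normal(0.0, 0.005, n_m)
    beta_sex = rng.normal(0.0, 0.1, n_m)

    bg_idx = np.array([mirnas.index(m) for m in background]) if background else np.array([], int)
    n_diff = min(cfg.n_diff_mirnas, len(bg_idx))
    diff_idx = rng.choice(bg_idx, size=n_diff, replace=False) if n_diff else np.array([], int)
    sp_effect = np.zeros(n_m)
    sp_effect[diff_idx] = cfg.mirna_log2fc * rng.choice([-1.0, 1.0], size=n_diff)

    # latent cell-type activities (log2 units)
    lam = rng.normal(0.0, cfg.lambda_noise_sd, size=(n_s, len(celltypes)))
    lam = pd.DataFrame(lam, index=meta["sample_id"], columns=celltypes)
    t_years = np.full(n_s, np.nan)
    for i, row in meta.iterrows():
        comp = row["compartment"]
        for ct in celltypes:
            if comp == "CSF" and ct in cfg.brain_celltypes:
                lam.iloc[i, celltypes.index(ct)] += cfg.compartment_loading
            if comp == "serum" and ct in cfg.immune_celltypes:
                lam.iloc[i, celltypes.index(ct)] += 0.3
        if bool(row["converter"]) and pd.notna(row["conversion_date"]):
            t = (pd.Timestamp(row["sample_date"]) - pd.Timestamp(row["conversion_date"])
                 ).days / DAYS_PER_YEAR
            t_years[i] = t
            bump = cfg.signature_strength * tent(np.array([t]), cfg.peak_width_years)[0]
            for ct in cfg.immune_celltypes:
                if ct in lam.columns:
                    lam.loc[row["sample_id"], ct] += bump
            if cfg.pericyte_celltype in lam.columns:
                lam.loc[row["sample_id"], cfg.pericyte_celltype] -= bump

    membership = np.zeros((n_m, len(celltypes)))
    for c, ct in enumerate(celltypes):
        for m in signatures[ct]:
            membership[mirnas.index(m), c] = 1.0

    s_j = rng.lognormal(mean=0.0, sigma=cfg.libsize_log_sd, size=n_s)
    is_sp = (meta["subtype"] == "SP").to_numpy(dtype=float)
    batch_codes = pd.Categorical(meta["batch"]).codes if "batch" in meta else np.zeros(n_s)
    batch_ind = (batch_codes % 2).astype(float)
    age = meta["age"].to_numpy(dtype=float)
    sex_m = (meta["sex"] == "M").to_numpy(dtype=float)

    eta = (
        sp_effect[:, None] * is_sp[None, :]
        + beta_batch[:, None] * batch_ind[None, :]
        + beta_age[:, None] * (age - age.mean())[None, :]
        + beta_sex[:, None] * sex_m[None, :]
        + membership @ lam.to_numpy().T
    )
    mean = s_j[None, :] * q[:, None] * np.exp(np.log(2.0) * eta)

    alpha = cfg.nb_dispersion
    if alpha < 1e-6:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / alpha
        counts = rng.poisson(rng.gamma(shape, mean * alpha))
    counts_df = pd.DataFrame(counts.astype(np.int64), index=mirnas,
                             columns=meta["sample_id"])
    batch = meta.set_index("sample_id")["batch"] if "batch" in meta else None
    cm = CountMatrix(counts_df, batch)

    mirna_truth = pd.DataFrame({
        "mirna_id": mirnas,
        "baseline_mean": q,
        "sp_log2fc": sp_effect,
        "is_signature": membership.any(axis=1),
        "differential": sp_effect != 0,
    })
    truth = {"mirna": mirna_truth, "lambda": lam, "size_factor_true": s_j,
             "t_years": t_years}
    return cm, truth
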