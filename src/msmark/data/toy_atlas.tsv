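cell_type	miR-100-5p	miR-101-3p	miR-103a-3p	miR-106b-5p	miR-107	miR-124-3p	miR-1246	miR-125b-5p	miR-126-3p	miR-1260a	miR-128-3p	miR-129-5p	miR-1298-5p	miR-130a-3p	miR-132-3p	miR-132-5p	miR-135a-5p	miR-137	miR-138-5p	miR-142-3p	miR-142-5p	miR-143-3p	miR-143-5p	miR-145-5p	miR-146a-5p	miR-150-5p	miR-151a-3p	miR-154-5p	miR-155-5p	miR-15a-5p	miR-15b-5p	miR-16-5p	miR-17-5p	miR-181a-5p	miR-181b-5p	miR-186-5p	miR-191-5p	miR-1911-5p	miR-195-5p	miR-199a-5p	miR-204-3p	miR-204-5p	miR-20a-5p	miR-21-5p	miR-214-3p	miR-219a-5p	miR-22-3p	miR-223-3p	miR-23b-3p	miR-24-3p	miR-25-3p	miR-26a-5p	miR-27a-3p	miR-28-5p	miR-29a-3p	miR-29b-3p	miR-30b-5p	miR-30c-5p	miR-30d-5p	miR-30e-5p	miR-31-5p	miR-320a	miR-323a-3p	miR-331-3p	miR-340-5p	miR-342-3p	miR-342-5p	miR-361-3p	miR-370-3p	miR-377-3p	miR-378a-3p	miR-382-5p	miR-410-3p	miR-425-5p	miR-451a	miR-484	miR-487b-3p	miR-497-5p	miR-504-5p	miR-532-5p	miR-652-3p	miR-885-5p	miR-9-5p	miR-92a-3p	miR-93-5p	miR-99a-5p
CD4_T	0.18	9.2	1.327	0.07	0.924	1.084	0.893	0.51	0.849	1.369	0.774	0.562	1.436	0.965	0.983	1.435	1.398	1.214	1.283	0.464	11.6	0.835	1.11	1.152	10.4	12.0	0.656	0.005	10.8	0.434	7.6	1.353	1.405	10.0	0.993	0.655	0.331	0.338	0.119	1.048	0.369	0.414	0.699	11.2	1.162	0.452	1.078	0.471	0.327	0.947	0.278	8.0	0.866	1.062	9.6	0.3	0.918	0.608	0.143	0.11	8.4	0.646	0.762	1.006	0.581	8.8	0.739	1.267	1.464	1.25	0.402	1.261	0.585	0.07	0.79	1.051	0.317	0.708	1.065	0.348	0.724	0.836	1.046	1.139	0.499	1.474
CD8_T	0.483	0.347	9.2	0.248	0.094	0.441	0.696	1.182	0.39	0.729	1.139	0.609	1.122	0.742	1.363	1.108	0.406	1.343	1.035	11.6	0.331	0.056	0.259	0.825	1.204	12.0	0.289	0.74	0.521	1.438	0.689	10.8	1.392	0.718	10.0	0.572	0.164	0.0	0.483	1.094	1.058	1.019	0.693	0.419	0.157	0.653	0.263	11.2	0.61	9.6	7.6	1.488	0.483	8.4	1.133	0.704	0.901	0.38	1.43	8.0	1.376	0.905	0.463	0.478	0.637	0.585	0.967	0.162	0.369	0.084	0.931	0.503	0.533	1.01	1.276	0.36	1.257	1.218	1.029	1.301	0.434	0.446	0.941	10.4	8.8	0.788
NK	1.105	0.35	0.009	0.721	8.4	0.537	1.032	0.735	9.6	1.075	1.116	0.61	0.012	7.6	0.091	0.959	0.239	1.222	1.321	1.177	1.225	1.394	0.877	0.221	0.128	12.0	0.313	0.731	1.399	9.2	0.378	0.828	0.559	10.8	0.89	1.314	0.677	0.235	1.354	0.992	0.425	0.765	8.8	0.597	0.684	0.1	0.984	0.892	8.0	0.469	0.227	0.474	0.248	0.861	0.404	1.039	10.4	11.6	1.43	0.529	0.021	0.292	0.105	0.664	1.474	1.204	1.123	0.821	0.448	0.082	11.2	0.593	0.619	1.062	10.0	1.076	0.536	0.361	0.87	0.862	0.564	1.455	1.263	0.953	1.149	0.079
B_cell	0.058	0.947	1.163	0.48	1.38	0.046	1.252	0.232	0.83	7.6	1.122	0.892	1.306	0.448	1.175	1.082	0.396	0.587	0.076	1.29	1.368	0.057	0.355	0.613	0.767	11.6	8.4	0.446	12.0	0.176	0.277	0.898	1.336	1.478	11.2	10.0	0.095	0.948	0.589	0.599	1.399	0.148	1.132	1.395	1.141	1.089	1.414	0.81	0.919	0.957	0.734	0.303	0.429	0.605	1.266	1.017	0.853	0.907	9.6	1.042	0.422	10.8	0.219	0.502	9.2	10.4	0.575	8.8	0.065	0.452	1.392	0.617	0.995	8.0	1.322	1.345	0.175	0.37	0.008	0.863	0.341	0.576	0.205	0.454	0.812	0.217
monocyte	0.528	0.704	1.451	9.6	0.363	0.375	0.041	0.664	1.065	1.281	0.155	0.079	1.479	0.575	11.2	0.681	0.122	0.115	0.362	0.556	1.455	0.632	0.87	0.742	11.6	0.135	0.318	1.351	0.049	0.029	0.298	1.013	10.0	1.281	0.048	0.244	8.4	0.36	0.96	0.302	1.405	0.421	0.28	1.049	0.811	0.612	10.8	12.0	0.824	1.263	1.2	0.281	10.4	0.946	1.097	1.385	0.37	1.117	1.4	0.736	0.962	0.782	1.356	1.376	1.328	0.05	8.0	0.403	0.519	0.892	0.619	0.74	0.627	0.865	0.434	8.8	0.638	1.125	1.13	7.6	9.2	0.44	0.721	0.687	0.868	0.43
neuron	1.059	0.503	0.653	0.297	1.394	11.6	0.821	0.251	0.818	0.397	11.2	9.2	10.8	0.052	1.118	0.809	1.367	10.4	8.8	1.45	0.465	0.009	1.418	0.836	1.086	0.528	0.3	0.794	0.198	1.002	0.35	0.895	1.483	0.222	0.817	1.109	1.361	9.6	0.734	1.146	1.328	0.372	0.909	0.711	1.413	10.0	0.359	0.677	0.246	0.726	0.191	0.247	0.468	1.254	0.048	0.068	1.381	0.089	0.994	0.72	0.212	0.717	8.4	0.283	1.067	0.214	0.572	1.319	8.0	0.988	1.355	0.195	0.716	1.241	1.049	0.51	7.6	0.71	0.226	1.084	0.55	1.294	12.0	0.899	1.058	0.392
astrocyte	9.6	0.635	0.725	1.195	0.243	11.6	8.0	10.8	0.66	0.399	0.539	1.076	0.656	1.309	0.206	0.835	10.0	0.051	0.104	0.34	1.19	10.4	0.431	0.065	0.367	0.803	1.48	1.3	0.536	1.457	0.27	0.43	0.899	1.267	1.34	0.411	0.923	0.1	0.659	0.631	9.2	0.938	1.26	0.269	0.348	0.564	0.481	0.111	0.063	1.409	1.201	0.349	1.412	0.792	0.364	12.0	1.482	0.428	0.51	0.98	1.328	1.046	0.208	8.8	1.154	0.121	1.214	1.06	0.749	0.529	0.609	0.73	0.92	1.402	0.693	1.035	1.247	0.247	7.6	0.859	1.454	8.4	0.131	0.305	0.886	11.2
pericyte	0.404	0.061	0.295	1.16	0.479	0.234	0.882	0.117	1.252	0.749	1.448	0.616	0.567	0.397	1.206	9.2	1.013	1.352	0.69	0.932	0.704	0.563	11.2	11.6	0.987	1.412	0.599	8.0	0.698	0.836	0.287	1.102	1.432	0.002	0.467	0.389	1.196	0.829	10.0	10.8	1.247	12.0	0.061	0.088	10.4	0.48	0.741	0.055	1.271	1.124	1.064	0.822	1.279	1.26	0.439	1.258	1.071	0.837	0.243	0.45	0.507	0.983	1.433	1.212	0.934	0.319	0.359	1.033	0.849	8.8	0.613	7.6	8.4	0.9	0.545	0.536	0.471	9.6	0.595	0.971	1.162	0.44	0.872	0.908	1.34	0.165
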