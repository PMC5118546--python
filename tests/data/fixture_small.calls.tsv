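gene_id	call	fold_change	pooled_p	p_cold_1	p_cold_2	p_cold_3	p_cold_4	q_cold_1	q_cold_2	q_cold_3	q_cold_4	dir_cold_1	dir_cold_2	dir_cold_3	dir_cold_4	n_significant_up	n_significant_down	in_all_samples
G0005	up	7.93002	0	0	0	0	0	0	0	0	0	up	up	up	up	4	0	0
G0004	up	5.13545	0	0	0	0	0	0	0	0	0	up	up	up	up	4	0	0
G0003	up	4.69944	0	0	0	0	0	0	0	0	0	up	up	up	up	4	0	0
G0002	up	4.69211	0	1.19121e-184	0	0	0	1.19121e-183	0	0	0	up	up	up	up	4	0	0
G0001	up	3.51795	0	0	0	0	0	0	0	0	0	up	up	up	up	4	0	0
G0011	up	1.47297	8.02802e-15	0.00340687	0.00602529	4.23773e-35	0.499788	0.00630902	0.0107594	1.92624e-34	0.623476	up	up	up	up	3	0	0
G0008	up	1.32583	2.63552e-23	0.000102017	1.52854e-14	9.06301e-41	0.644086	0.000242897	4.77669e-14	4.53151e-40	0.685198	up	up	up	down	3	0	0
G0050	down	0.776815	1.15592e-12	0.00131936	4.99683e-08	3.23516e-18	0.570723	0.00263872	1.31496e-07	1.01099e-17	0.634136	down	down	down	down	0	3	0
G0025	down	0.727689	2.81319e-31	9.52141e-59	7.26107e-36	0.000104667	0.0506779	7.93451e-58	3.63054e-35	0.000218056	0.0873756	down	down	down	up	0	3	0
G0040	down	0.714323	4.37751e-71	2.34687e-25	0.0205926	5.87292e-70	3.81713e-45	1.30382e-24	0.029418	4.19495e-69	2.72652e-44	down	down	down	down	0	4	0
G0016	down	0.672786	1.23517e-28	0.429477	4.12656e-49	1.60863e-19	3.01465e-05	0.477197	2.94754e-48	5.36209e-19	6.85147e-05	down	down	down	down	0	3	0
G0037	down	0.554643	9.74336e-77	4.12594e-57	1.57391e-16	3.35118e-41	2.67548e-15	2.9471e-56	5.24637e-16	1.86177e-40	1.11478e-14	down	down	down	down	0	4	0
G0009	unchanged	1.68949	0.0399148	0.0413494	0.0142939	0.517111	0.826703	0.0646084	0.0210204	0.615608	0.843575	up	up	up	up	1	0	0
G0026	unchanged	1.42769	0.0170103	0.148758	0.000561975	0.000282675	1	0.190715	0.00123396	0.000543605	1	down	up	up	down	2	0	0
G0015	unchanged	1.36559	0.00817857	0.0948157	0.00638316	0.927399	0.0150208	0.135451	0.0110054	0.966041	0.0300416	up	up	down	up	2	0	0
G0010	unchanged	1.32916	1.08827e-11	6.1985e-19	9.69185e-05	1.37694e-22	2.53058e-14	2.58271e-18	0.000230758	4.91764e-22	9.73299e-14	up	up	up	down	3	1	0
G0049	unchanged	1.32157	6.74449e-07	0.51921	0.103046	2.18627e-10	4.69861e-14	0.564359	0.135587	5.75334e-10	1.67807e-13	down	down	up	up	2	0	0
G0029	unchanged	1.28995	0.0420505	1	0.555326	5.24871e-09	0.383737	1	0.590773	1.31218e-08	0.491971	down	down	up	down	1	0	0
G0032	unchanged	1.15916	0.00285089	0.00233813	7.34217e-05	0.162422	2.29589e-09	0.00449641	0.000183554	0.225586	6.75262e-09	up	down	up	up	2	1	0
G0044	unchanged	1.13344	4.7167e-13	1.73119e-48	3.6322e-27	6.3464e-80	2.14918e-18	1.08199e-47	1.51342e-26	5.28867e-79	9.76899e-18	up	down	up	down	2	2	0
G0034	unchanged	1.12792	0.00778258	2.29836e-05	0.15311	1.95884e-23	1.41744e-18	6.38435e-05	0.191388	7.53398e-23	7.08718e-18	up	up	down	up	2	1	0
G0047	unchanged	1.12673	2.05812e-09	0.160707	0.00277011	1.05725e-17	1.12176e-79	0.200884	0.00512983	3.10957e-17	9.348e-79	down	up	down	up	2	1	0
G0023	unchanged	1.12336	0.502809	0.287071	0.504062	0.639418	0.511251	0.333803	0.547893	0.743509	0.623476	up	up	down	up	0	0	0
G0035	unchanged	1.10013	0.140892	0.046542	0.602344	0.000382569	0.158871	0.0705182	0.627441	0.000708462	0.248236	down	up	up	up	1	0	0
G0021	unchanged	1.09914	0.000690713	9.1853e-07	3.30713e-38	0.151232	0.0430244	2.70156e-06	1.8373e-37	0.220433	0.0768292	down	up	up	down	1	1	0
G0027	unchanged	1.0788	0.207507	0.18442	0.0712134	0.0503335	0.130089	0.224903	0.0962343	0.0838891	0.209821	up	down	up	up	0	0	0
G0041	unchanged	1.04768	0.528821	3.44157e-19	2.40577e-18	5.29949e-07	2.85603e-09	1.56435e-18	9.25297e-18	1.20443e-06	7.93341e-09	down	up	up	down	2	2	0
G0028	unchanged	1.04507	1	0.256301	0.270073	0.838474	0.551182	0.30512	0.314038	0.891994	0.626343	down	up	down	up	0	0	0
G0019	unchanged	1.00036	1	0.0163015	4.02669e-32	0.415681	3.51274e-31	0.0262927	1.83031e-31	0.532924	1.95152e-30	down	up	up	down	1	2	0
G0012	unchanged	0.994932	0.752765	0.00877485	0.0071012	0.154303	0.342675	0.0156694	0.0118353	0.220433	0.463074	down	up	up	down	1	1	0
G0018	unchanged	0.983666	0.5068	1.07562e-15	0.0021946	0.367105	0.278765	3.84151e-15	0.00422039	0.483033	0.398235	down	up	up	up	1	1	0
G0024	unchanged	0.981812	0.853044	7.14363e-05	0.000567622	4.5863e-07	0.258262	0.000178591	0.00123396	1.09198e-06	0.379797	down	down	up	up	1	2	0
G0046	unchanged	0.978125	0.940708	1	0.238809	1	0.545068	1	0.284297	1	0.626343	down	up	down	down	0	0	0
G0031	unchanged	0.966386	0.68445	0.000192544	0.184423	0.468799	0.000782432	0.0004376	0.224906	0.571706	0.00170094	up	down	down	down	1	1	0
G0042	unchanged	0.93227	0.619819	0.000381643	0.0106254	0.437392	0.00105249	0.00082966	0.0161253	0.54674	0.00219269	down	down	up	up	1	2	0
G0007	unchanged	0.921748	0.73004	7.05322e-08	0.0569006	0.690549	6.32957e-07	2.20413e-07	0.0790286	0.784714	1.66568e-06	down	down	up	up	1	1	0
G0045	unchanged	0.907424	0.360779	0.660029	0.359294	1	0.100951	0.702159	0.399216	1	0.168252	up	down	down	down	0	0	0
G0017	unchanged	0.895846	0.0134014	4.22281e-05	8.39756e-10	0.00511067	3.89173e-10	0.000111127	2.46987e-09	0.00881149	1.21617e-09	down	up	down	down	1	3	0
G0020	unchanged	0.8748	2.63724e-07	0.141725	2.23672e-44	8.89947e-26	3.15791e-12	0.18648	1.39795e-43	3.70811e-25	1.05264e-11	up	down	down	up	1	2	0
G0038	unchanged	0.862368	0.000332452	3.94322e-16	0.00872548	0.000604027	0.0187154	1.51662e-15	0.0140734	0.00107862	0.0359912	down	down	up	down	1	3	0
G0006	unchanged	0.82901	0.00127248	0.0148543	0.0106427	1.50399e-11	0.042958	0.0247572	0.0161253	4.17775e-11	0.0768292	down	up	down	down	1	2	0
G0048	unchanged	0.809189	0.168791	0.34074	0.33245	0.204194	2.76136e-06	0.387205	0.377784	0.275937	6.57467e-06	up	up	down	down	0	1	0
G0030	unchanged	0.790294	9.08207e-26	0.0127437	2.34497e-56	0.0686165	4.66382e-36	0.0219718	1.95414e-55	0.107213	2.91489e-35	up	down	down	down	1	2	0
G0039	unchanged	0.786923	4.05279e-24	2.59729e-22	7.96895e-09	1.21749e-59	1.19259e-06	1.29865e-21	2.2136e-08	7.60933e-59	2.98147e-06	down	down	down	up	1	3	0
G0022	unchanged	0.780097	3.09378e-10	1.2541e-09	2.48558e-17	0.796864	0.19848	4.18035e-09	8.87707e-17	0.866156	0.300727	down	down	down	down	0	2	0
G0014	unchanged	0.774005	0.000673611	0.956172	0.000634375	7.02453e-05	0.291264	0.996013	0.00132161	0.000152707	0.404534	down	down	down	down	0	2	0
G0043	unchanged	0.746425	0.0523409	0.1361	0.833035	0.000190478	0.682305	0.183918	0.850036	0.000380957	0.710734	down	down	down	up	0	1	0
G0013	unchanged	0.719738	0.00136987	0.106013	0.000729721	0.0631212	0.3832	0.14724	0.00145944	0.101808	0.491971	down	down	down	down	0	1	0
G0033	unchanged	0.650953	0.0710861	0.0725402	1	0.0985644	0.529751	0.106677	1	0.14934	0.626343	down	down	down	down	0	0	0
G0036	unchanged	0.61679	0.0652774	0.00074324	0.148845	0.732827	0.620927	0.00154842	0.190827	0.814252	0.674921	down	down	down	up	0	1	0
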