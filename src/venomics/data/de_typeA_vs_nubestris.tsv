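toxin	baseMean	log2FoldChange	lfcSE	stat	p_value	p_adj
SVSP-4	56149.550	-2.041	0.790	-2.582	0.010	0.136
SVSP-1	62813.029	-2.650	0.676	-3.920	<0.001	0.003
SVSP-2	14843.268	-0.759	0.651	-1.166	0.243	0.819
SVSP-6	31232.805	-1.245	0.643	-1.935	0.053	0.405
SVSP-7	10256.001	-2.901	0.713	-4.069	<0.001	0.002
SVSP-3	21197.683	-0.765	0.534	-1.433	0.152	0.685
SVSP-8	24729.723	13.915	1.148	12.121	<0.001	<0.001
VEGF-2	575.456	0.408	0.512	0.798	0.425	0.968
VEGF-4	176.204	-0.412	0.432	-0.953	0.341	0.913
VEGF-3	329.392	0.240	0.558	0.429	0.668	0.983
CTL-2	21966.999	1.227	0.588	2.087	0.037	0.322
CTL-1	75597.100	13.412	0.619	21.666	<0.001	<0.001
SVMPII-3	26046.537	7.004	3.014	2.324	0.020	0.228
SVMPII-2	58055.510	4.545	0.471	9.658	<0.001	<0.001
CTL-3	27445.563	2.004	0.682	2.940	0.003	0.061
LAAO-1	81941.767	4.437	0.564	7.862	<0.001	<0.001
NGF-1	17559.052	1.241	0.606	2.047	0.041	0.350
NUC-1	24635.841	0.0662	0.630	0.105	0.916	0.999
PDE-1	22815.921	1.204	0.537	2.242	0.025	0.258
PLA2-1	153799.239	-5.920	0.508	-11.652	<0.001	<0.001
PLA2-2	193031.819	-7.691	1.132	-6.796	<0.001	<0.001
SVMPIII-5	1120896.609	2.273	0.848	2.681	0.007	0.115
SVMPIII-3	146258.094	6.755	0.495	13.645	<0.001	<0.001
SVMPIII-2	68851.762	5.381	0.499	10.779	<0.001	<0.001
SVMPIII-4	96830.991	1.714	0.522	3.286	0.001	0.025
SVSP-5	12727.207	2.176	0.638	3.408	0.001	0.019
SVMPII-1	75173.762	4.756	0.534	8.899	<0.001	<0.001
BPP-1	162148.870	-0.756	1.137	-0.665	0.506	0.982
HYAL-1	3084.833	2.260	0.587	3.853	<0.001	0.004
SVMPIII-1	676.400	-1.536	2.179	-0.705	0.481	0.982
VEGF-1	19141.242	-3.323	1.095	-3.036	0.002	0.050
Waprin-1	65.350	-0.587	0.626	-0.938	0.348	0.915
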