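toxin	baseMean	log2FoldChange	lfcSE	stat	p_value	p_adj
SVSP-4	17900.673	1.529	0.879	1.740	0.082	0.327
SVSP-1	23976.545	-0.846	0.744	-1.136	0.256	0.562
SVSP-2	17011.775	-1.609	0.720	-2.234	0.025	0.171
SVSP-6	15736.775	0.634	0.743	0.854	0.393	0.704
SVSP-7	3569.069	-0.970	0.718	-1.351	0.177	0.483
SVSP-3	13267.220	0.373	0.656	0.569	0.570	0.805
SVSP-8	61332.390	-1.966	0.681	-2.886	0.004	0.053
VEGF-2	398.593	1.786	0.519	3.445	0.001	0.012
VEGF-4	113.051	0.845	0.535	1.580	0.114	0.391
VEGF-3	218.467	1.899	0.590	3.220	0.001	0.021
CTL-2	15138.097	7.366	0.698	10.557	<0.001	<0.001
CTL-1	68552.480	2.542	0.432	5.890	<0.001	<0.001
SVMPII-3	40750.244	-0.784	3.020	-0.260	0.795	0.908
SVMPII-2	67043.525	0.277	0.433	0.641	0.522	0.780
CTL-3	25464.314	0.979	0.707	1.384	0.166	0.469
LAAO-1	77794.353	1.648	0.514	3.206	0.001	0.022
NGF-1	13847.466	1.826	0.701	2.606	0.009	0.088
NUC-1	23423.714	-0.436	0.683	-0.638	0.523	0.782
PDE-1	27866.068	-0.637	0.571	-1.115	0.265	0.572
PLA2-1	50595.962	-4.499	0.465	-9.673	<0.001	<0.001
PLA2-2	90982.168	-6.867	2.083	-3.296	0.001	0.018
SVMPIII-5	1147158.941	0.489	0.697	0.702	0.483	0.766
SVMPIII-3	202400.932	-0.410	0.438	-0.937	0.349	0.661
SVMPIII-2	70220.557	1.077	0.453	2.377	0.017	0.134
SVMPIII-4	111332.469	-0.222	0.472	-0.470	0.638	0.837
SVSP-5	10829.466	1.964	0.726	2.707	0.007	0.074
SVMPII-1	77902.986	0.911	0.480	1.898	0.058	0.273
BPP-1	120779.234	-0.334	2.184	-0.153	0.878	0.954
HYAL-1	3203.542	0.434	0.624	0.696	0.487	0.767
SVMPIII-1	236.935	4.758	2.234	2.130	0.033	0.197
VEGF-1	2696.561	4.593	1.031	4.457	<0.001	<0.001
Waprin-1	51.896	-0.411	0.679	-0.606	0.545	NA
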