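species	genome_size	lsc	irb	ssc	ira
S. angustifolium	151305	80790	26177	18161	26177
I. dichotoma	153573	83071	26181	18140	26181
I. domestica	153730	83137	26199	18195	26199
I. koreana	153055	82579	26094	18288	26094
I. ensata	150947	81514	25549	18335	25549
I. lactea	152294	82159	26023	18089	26023
I. laevigata	151081	81144	26022	17893	26022
I. minutoaurea	150955	81516	25549	18341	25549
I. odaesanensis	153620	82777	26784	17275	26784
I. pseudoacorus	152562	82786	25948	17880	25948
I. rossii var. latifolia	152654	82212	26183	18076	26183
I. rossii var. rossii	153083	82635	26183	18082	26183
I. ruthenica	152287	82311	25920	18136	25920
I. setosa	152921	82900	26067	17887	26067
I. uniflora var. caricina	152281	82307	25920	18134	25920
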