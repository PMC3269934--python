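MI:0007	anti tag coimmunoprecipitation	E05.196.150.639	Co-Immunoprecipitation
MI:0006	anti bait coimmunoprecipitation	E05.196.150.639	Co-Immunoprecipitation
MI:0096	pull down	E05.196.181.400.170	Affinity Chromatography
MI:0018	two hybrid	E05.393.220.870	Two-hybrid System Techniques
MI:0114	X-ray crystallography	E05.196.309.742.225	X-Ray Crystallography
MI:0071	Molecular Sieving	E05.196.181.400.250	Molecular Sieve Chromatography
MI:0416	Fluorescence Microscopy	E01.370.350.515.458	Fluorescence Microscopy
MI:0424	Protein Kinase Assay	E05.196.630.570.700	Protein Array Analysis
MI:0107	Surface Plasmon Resonance	E05.196.890	Surface Plasmon Resonance
MI:0663	Confocal Microscopy	E01.370.350.515.395	Confocal Microscopy
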