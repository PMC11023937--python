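type	size_class	n_clusters
DNA-only	2	13111228
DNA-only	3+	5033182
RNA-DNA	2	1009706
RNA-DNA	3-10	783709
RNA-DNA	>10	607977
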