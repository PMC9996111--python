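region_a	region_b	t
left precentral	left thalamus (MD)	3.53
left precentral	left thalamus (LP-VP)	3.68
left precentral	left thalamus (PuM)	3.54
left precentral	left thalamus (VP-VL)	3.56
left postcentral	left thalamus (LP-VP)	3.73
left postcentral	left thalamus (VL)	3.51
left supramarginal	left thalamus (VL)	3.53
left postcentral	left thalamus (VP-VL)	3.55
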