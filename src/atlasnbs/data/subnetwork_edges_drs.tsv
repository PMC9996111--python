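region_a	region_b	t
right caudal middle frontal	left superior frontal	3.72
left pars opercularis	left superior frontal	4.09
left rostral middle frontal	left superior frontal	4.18
right caudal middle frontal	left caudal middle frontal	3.63
left rostral middle frontal	left caudal middle frontal	3.70
right superior frontal	left precentral	3.67
right caudal middle frontal	left precentral	3.60
right paracentral	left precentral	3.62
left rostral middle frontal	left precentral	3.67
left superior frontal	left precentral	4.13
left caudal middle frontal	left precentral	3.66
left precentral	left postcentral	4.04
right precuneus	left supramarginal	3.56
right isthmus cingulate	left superior parietal	3.84
right superior parietal	left superior parietal	3.88
right precuneus	left superior parietal	3.77
left superior frontal	left superior parietal	3.60
left postcentral	left superior parietal	3.73
right isthmus cingulate	left inferior parietal	3.69
right precuneus	left inferior parietal	3.51
left superior parietal	left lateral occipital	3.57
right isthmus cingulate	left inferior temporal	3.56
left superior frontal	left insula	3.90
left precentral	left insula	3.74
left postcentral	left insula	3.67
right inferior parietal	left thalamus (Pul)	3.53
right precuneus	left thalamus (Pul)	3.65
left precentral	left thalamus (MD)	3.54
left precentral	left thalamus (LP-VP)	3.72
left precentral	left thalamus (PuM)	3.53
left precentral	left thalamus (VP-VL)	3.58
left precentral	left caudate	3.65
right isthmus cingulate	left putamen	3.77
right inferior parietal	left putamen	3.60
right precuneus	left putamen	3.70
right lateral occipital	left putamen	3.57
left superior frontal	left putamen	3.85
left precentral	left putamen	3.78
left postcentral	left putamen	3.71
left precentral	left pallidum	3.66
left precentral	brain stem	3.54
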