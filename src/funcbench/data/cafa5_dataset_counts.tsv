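# Published composition of the CAFA5 prospective evaluation datasets.
# One row per (dataset, setting): evaluable protein count and propagated,
# root-excluded ground-truth term counts per GO aspect.
# "total" protein rows de-duplicate proteins appearing in several settings.
# The full-dataset PK aspect split is the one implied by the published row
# and column marginals.
# post_t0_unique rows count unique (pre-propagation) annotations added after
# the submission deadline and the subset citing post-deadline publications;
# aspect columns do not apply there.
dataset	setting	proteins	terms_bpo	terms_cco	terms_mfo
full	NK	1717	21033	10343	4182
full	LK	2294	23046	7943	4633
full	PK	21415	117331	23963	22055
full	total	24405	161410	42249	30870
head_to_head	NK	1102	13399	5771	2072
head_to_head	LK	1769	18586	4819	2850
head_to_head	PK	15732	87100	14921	15126
head_to_head	total	17818	119085	25511	20048
unpublished	NK	272	3540	1222	562
unpublished	LK	351	4016	726	1074
unpublished	PK	1073	8689	2298	1190
unpublished	total	1568	16245	4246	2826
post_t0_unique	all	0	68940	0	0
post_t0_unique	published_after_t0	0	3627	0	0
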