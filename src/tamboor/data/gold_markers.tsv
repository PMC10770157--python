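# Curated directional gold list for evaluating PD metabolite-biomarker
# predictions: 25 high-confidence secretion-level changes (each backed by
# at least two experimental studies) plus the 5 well-known PD metabolite
# alterations. direction is the change in PD relative to control.
# detected_by records which reference algorithm(s) recovered the entry in
# the published reference analysis: original_timbr, modified_timbr,
# tamboor, combinations joined with '+', 'all', or 'none'.
metabolite_id	direction	source	detected_by
quinolinate	increased	high_confidence	original_timbr
kynurenine	increased	high_confidence	original_timbr
Fe3+	increased	high_confidence	original_timbr
hydroxide	increased	high_confidence	original_timbr
prostaglandins	increased	high_confidence	original_timbr
salsolinol	increased	high_confidence	tamboor
1,2-dehydrosalsolinol	increased	high_confidence	tamboor
acetone	increased	high_confidence	tamboor
vanil-lactate	increased	high_confidence	tamboor
formate	increased	high_confidence	tamboor
urea	increased	high_confidence	tamboor
(R)-mevalonate	increased	high_confidence	tamboor
biliverdin	increased	high_confidence	tamboor
4-methyl-2-oxopentanoate	increased	high_confidence	original_timbr+tamboor
ApoA1	decreased	high_confidence	original_timbr
5-hydroxyindoleacetate	decreased	high_confidence	original_timbr
lanosterol	decreased	high_confidence	original_timbr
3-methoxytyramine	decreased	high_confidence	original_timbr
lysine	decreased	high_confidence	modified_timbr
GSH	decreased	high_confidence	modified_timbr
calcitriol	decreased	high_confidence	tamboor
nicotinamide	decreased	high_confidence	tamboor
carnosine	decreased	high_confidence	tamboor
albumin	decreased	high_confidence	original_timbr+tamboor
thiamin-P	decreased	high_confidence	all
lactate	increased	well_known	original_timbr+tamboor
glutamate	increased	well_known	none
dopamine	decreased	well_known	original_timbr+tamboor
serotonin	decreased	well_known	original_timbr+tamboor
eumelanin	decreased	well_known	modified_timbr
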