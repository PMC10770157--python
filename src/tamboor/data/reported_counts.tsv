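# Reference per-algorithm prediction counts from the published
# 14-comparison analysis (percentile 0.25, min support 7 of 14).
# n_total_reported is the printed total-prediction count; for tamboor the
# printed value (273) differs by one from n_increased + n_decreased (274),
# an inconsistency in the source table that is preserved here as printed.
algorithm	n_increased	n_decreased	n_total_reported	n_high_confidence_detected	n_well_known_detected
original_timbr	184	185	369	12	3
modified_timbr	178	121	299	3	1
tamboor	118	156	273	14	3
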