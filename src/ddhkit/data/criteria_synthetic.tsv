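# SYNTHETIC transcription template for the normative acetabular-index table.
# These strata and numbers are placeholders with the required schema; replace
# them with values transcribed from a published normative reference before
# clinical use.  Age brackets are half-open: [age_min, age_max) years.
nationality	sex	side	age_min	age_max	mean_deg	sd_deg
chinese	female	either	0.4	2.0	24.0	4.0
chinese	female	either	2.0	8.0	23.0	4.0
chinese	male	either	0.4	2.0	23.0	4.0
chinese	male	either	2.0	8.0	22.0	4.0
other	female	either	0.4	2.0	25.0	4.0
other	female	either	2.0	8.0	24.0	4.0
other	male	either	0.4	2.0	24.0	4.0
other	male	either	2.0	8.0	23.0	4.0
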