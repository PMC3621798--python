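>MbnA_OB3b Methylosinus trichosporium OB3b precursor peptide
MTVKIAQKKVLPVIGRAAALCGSCYPCSCM
>MbnA_rosea Methylocystis rosea SV97T precursor peptide
MTIRIAKRITLNVIGRASARCASTCAATNG
>MbnA_strainM_syn synthetic reconstruction: rosea-like leader + strain M core
MTIRIAKRITLNVIGRASARCASTCAMTNG
>MbnA_hirsuta_syn synthetic reconstruction: rosea-like leader + hirsuta core
MTIRIAKRITLNVIGRASAMCASTCAATNG
>MbnA_groupV_syn synthetic single-cysteine Group V-like precursor
MTAKIAQRKTLPVIGRAAALCGSTAHTEAG
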