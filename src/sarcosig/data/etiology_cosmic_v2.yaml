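# Etiology annotation for the 30 COSMIC v2 signatures.
# Editable: keys must match the column names of the signature matrix in use.
# "aging" = spontaneous deamination of 5-methylcytosine at CpG sites.
Signature.1: aging
Signature.2: APOBEC
Signature.3: HRD
Signature.4: smoking
Signature.5: unknown
Signature.6: MMR
Signature.7: UV
Signature.8: unknown
Signature.9: POLH
Signature.10: POLE
Signature.11: temozolomide
Signature.12: unknown
Signature.13: APOBEC
Signature.14: unknown
Signature.15: MMR
Signature.16: unknown
Signature.17: unknown
Signature.18: unknown
Signature.19: unknown
Signature.20: MMR
Signature.21: MSI
Signature.22: aristolochic_acid
Signature.23: unknown
Signature.24: aflatoxin
Signature.25: unknown
Signature.26: MMR
Signature.27: unknown
Signature.28: unknown
Signature.29: tobacco_chewing
Signature.30: unknown
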