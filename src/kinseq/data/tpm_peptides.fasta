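>ENALDRAEQAEADK gene=TPM1 note=paralogue-pair-A
ENALDRAEQAEADK
>ENAIDRAEQAEADK gene=TPM2 note=paralogue-pair-A
ENAIDRAEQAEADK
>VIESRAQK gene=TPM1 note=paralogue-pair-B
VIESRAQK
>VIENRAMK gene=TPM2 note=paralogue-pair-B
VIENRAMK
>SLMASEEEYSTK gene=TPM2 note=spliceform-exon6
SLMASEEEYSTK
>TIDDLEETLASAK gene=TPM2 note=spliceform-exon10
TIDDLEETLASAK
>TIDDLEDEVYAQK gene=TPM2 note=spliceform-exon11
TIDDLEDEVYAQK
>TIDDLEDEVpYAQK ptm=10:phospho gene=TPM2 note=phosphopeptidoform
TIDDLEDEVYAQK
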