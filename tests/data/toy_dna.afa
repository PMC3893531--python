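>s1
ACGGT
>s2
ACG-T
>s3
AC-GT
>s4
ACGGA
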