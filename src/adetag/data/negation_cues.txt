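no
not
without
denies
denied
never
absence of
free of
ruled out
negative for
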