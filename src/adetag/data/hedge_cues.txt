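possibly
possible
presumed
suspected
suspicion of
could
may
might
unlikely
probable
probably
appears
apparently
likely
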