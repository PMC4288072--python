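however
due to
because
because of
after
before
prior to
subsequently
although
therefore
following
as a result of
during
since
when
while
despite
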