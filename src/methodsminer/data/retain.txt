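between
against
before
after
within
above
below
over
under
per
not
no
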