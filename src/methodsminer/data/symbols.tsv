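<=	less-than-or-equal-to
>=	greater-than-or-equal-to
≤	less-than-or-equal-to
≥	greater-than-or-equal-to
%	percent
<	less-than
>	greater-than
±	plus-or-minus
=	equal-to
α	alpha
β	beta
χ	chi
×	times
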