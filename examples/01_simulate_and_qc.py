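"""Generate synthetic class spectra and apply the transmission QC rule.

A pellet spectrum is usable when the achieved transmission reaches 60% and
its strongest band bottoms out between 10 and 30 %T; too-concentrated and
too-dilute preparations both fail.
"""

import tristepir as t

templates = t.default_templates()
for name, tpl in templates.items():
    spectrum = t.generate_spectrum(tpl, seed=1)
    pct = t.absorbance_to_percent_transmittance(spectrum)
    verdict = t.qc_accept(pct)
    status = "ACCEPT" if verdict.accepted else "REJECT " + "; ".join(verdict.reasons)
    print(f"{name:>6}: max %T = {verdict.max_percent_T:5.1f}, "
          f"min %T = {verdict.min_percent_T:5.1f}  ->  {status}")

print("\nmax %T >= 60 shows the pellet transmits enough light; min %T in "
      "[10, 30] shows the strongest band is neither saturated nor too weak.")
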