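"""qPCR arithmetic: ddCt fold change, standard curve, absolute copies.

Reproduces the comparative-Ct and absolute-quantification arithmetic on the
packaged miR-100 copy-number table, and fits a dilution-series standard
curve from a perfect two-fold series.
"""
import exomir

# ddCt: exosome vs cell, U6-referenced
exo = exomir.QPCRMeasurement("exo", target_cts=[25.1, 25.0, 24.9], reference_cts=[20.0] * 3)
cell = exomir.QPCRMeasurement("cell", target_cts=[24.0] * 3, reference_cts=[22.0] * 3)
fc, ddct = exomir.ddct_fold_change(exo, cell)
print(f"ddCt = {ddct:.2f}, fold change = {fc:.3f} "
      "(<1: miRNA retained in cells, >1: exported)")

# standard curve: nine 2-fold dilutions from 50 pM
top = exomir.picomolar_to_copies_per_ul(50.0)
series = [(top / 2**k, [12.0 + k] * 3) for k in range(9)]
curve = exomir.fit_standard_curve(series)
print(f"standard curve: slope {curve.slope:.4f} Ct/log10(copies), "
      f"r^2 {curve.r_squared:.4f}, efficiency {curve.efficiency:.2%}")
query = top / 20  # a concentration inside the fitted dilution range
print(f"a Ct of {curve.predict_ct(query):.2f} corresponds to "
      f"{exomir.absolute_copies(curve.predict_ct(query), curve):.3g} copies/ul")

# percent increase of transferred miR-100 from the packaged copy numbers
cp = exomir.load_copy_numbers().set_index("condition")
base = exomir.CopyEstimate("no donor", cp.loc["no donor", "copies"], cp.loc["no donor", "sem"])
ctl = exomir.CopyEstimate("AI-CTL", cp.loc["AI-CTL", "copies"], cp.loc["AI-CTL", "sem"])
ai = exomir.CopyEstimate("AI-100", cp.loc["AI-100", "copies"], cp.loc["AI-100", "sem"])
pct_ctl, sem_ctl = exomir.percent_increase(ctl, base)
pct_ai, sem_ai = exomir.percent_increase(ai, base)
print(f"miR-100 increase with control-antagomir donors: {pct_ctl:.1f}% +/- {sem_ctl:.1f}")
print(f"miR-100 increase with miR-100-antagomir donors: {pct_ai:.1f}% +/- {sem_ai:.1f}")
print("Blocking miR-100 in donor cells collapses the transfer effect.")
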