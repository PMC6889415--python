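"""Fit the Hill model to protein-lipid overlay dose-response curves.

Builds noiseless binding curves for the oxidized and reduced Akt2 PH
domain at the six spotted PIP3 amounts (100, 50, 25, 10, 5, 1 pmol) and
fits the four-parameter Hill equation by nonlinear least squares. The
fitted EC50 (midpoint amount, pmol) and Hillslope (cooperativity) show
that oxidation roughly halves the EC50 — the oxidized PH domain binds
PIP3 with markedly higher apparent affinity.
"""

from aktredox import fit_hill, generate_hill_curve

for condition, ec50, slope in [("oxidized", 28.84, 2.407), ("reduced", 52.30, 1.908)]:
    curve = generate_hill_curve(ec50, slope, top=1.0, bottom=0.0, condition=condition)
    fit = fit_hill(curve)
    print(
        f"{condition:>8} PH domain: EC50 = {fit.ec50:.2f} pmol, "
        f"Hillslope = {fit.hillslope:.3f} (RSS {fit.rss:.2e})"
    )
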