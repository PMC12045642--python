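"""Full pipeline: study bundle → VeDBA–Ṁ_O2 mixed-model calibration.

Runs every stage on a default synthetic study and prints the quantities a
calibration experiment reports: the pooled power fit (whose intercept is
the standard metabolic rate), the random-intercept mixed model of Ṁ_O2
against VeDBA with marginal/conditional R², and a prediction for a new
VeDBA observation.
"""

import tempfile
from pathlib import Path

from videba.calibration import predict_mo2
from videba.pipeline import RunConfig, run_all
from videba.synthetic import make_study

with tempfile.TemporaryDirectory() as td:
    sidecar = make_study(Path(td) / "study", seed=0)
    res = run_all(RunConfig(study_dir=str(Path(td) / "study"), out_dir=str(Path(td) / "out")))

p = res["power_pooled"]
print(f"pooled power fit: MO2 = {p.a:.2f} + {p.b:.3f}*U^{p.c:.2f}  (SMR = {p.a:.1f})")
fit = res["lmm_mo2"]
print(f"mixed model: MO2 = {fit.beta0:.1f} + {fit.beta1:.1f}*VeDBA + u_i"
      f"  (slope se {fit.se_beta1:.1f}, ddf {fit.ddf:.1f}, p = {fit.pvalue:.2g})")
print(f"R2 marginal {fit.r2_marginal:.2f} (fixed effect), "
      f"conditional {fit.r2_conditional:.2f} (fixed + individual intercepts)")
chi2, p_lrt = res["lrt_random_effect"]
print(f"random-intercept LRT: chi2 = {chi2:.1f}, p = {p_lrt:.2g}")
print(f"true slope kappa = {sidecar['individuals']['A']['kappa']}")

pred = predict_mo2(fit, 0.2, individual="A", interval="prediction")
print(f"predicted MO2 at VeDBA = 0.2 g for fish A: {pred['predicted'].iloc[0]:.1f} "
      f"[{pred['lo'].iloc[0]:.1f}, {pred['hi'].iloc[0]:.1f}] mg O2/kg/h")
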