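"""VeDBA from a trajectory: closed-form check and interval summary.

A point moving on a circle of radius 5 cm at one revolution per second has
constant acceleration rω² = 1.974 m/s² = 0.2013 g; the forward
finite-difference stencil recovers it from 90 fps samples to well within
its second-order truncation error.
"""

import numpy as np

from videba.types import G_CM_S2, Trajectory3D
from videba.vedba import finite_diff_accel, summarize_vedba, vedba

fps, r, w = 90.0, 5.0, 2 * np.pi
t = np.arange(450) / fps
traj = Trajectory3D(t=t, x=r * np.cos(w * t), y=r * np.sin(w * t), z=np.zeros_like(t),
                    valid=np.ones(len(t), bool), fps=fps)
series = vedba(finite_diff_accel(traj))
summary = summarize_vedba(series, lower=0.001, upper=1.0)

expected = r * w**2 / G_CM_S2
print(f"closed form: r*omega^2 = {expected:.4f} g")
print(f"mean measured VeDBA:   {summary.mean_vedba:.4f} g over {summary.n_included} frames")
print(f"excluded: {summary.n_excluded_high} above 1 g, {summary.n_excluded_low} below 0.001 g, "
      f"{summary.n_invalid} invalid (stencil needs 4 consecutive valid frames)")
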