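"""Response-vector labels and the tiny ROI detector.

The ROI stage does not regress wall positions directly. Instead each
frame gets a "response vector" — a piecewise-quadratic bump that is 1 at
the lumen center and falls to 0 at the midpoints between the center and
each wall — and a 1210-parameter two-conv network regresses that map.
The argmax of its (average-pooled) output is the lumen-center estimate.

Run:  python examples/02_labels_and_roi_detector.py   (~1 min)
"""

import numpy as np

import lumenflow as lf
from lumenflow.preprocess import envelope_stack
from lumenflow.training import TrainConfig

# --- labels ---------------------------------------------------------------
r = lf.response_vector(anterior=280, posterior=320, length=1020)
print("response vector around a lumen at 300 with walls at 280/320:")
print(f"  R[300] = {r[300]}   (center)")
print(f"  R[295] = {r[295]}   (quarter point)")
print(f"  R[290] = {r[290]}   (cut-off)")

# --- a small training cohort ----------------------------------------------
cohort = lf.make_cohort(n_subjects=2, frames_per_subject=300, master_seed=11)
env = np.concatenate([envelope_stack(s.rf.samples).T for s in cohort.subjects])
walls = np.concatenate(
    [np.column_stack([s.annotation.anterior, s.annotation.posterior])
     for s in cohort.subjects])

detector, history = lf.train_roi(
    env.astype(np.float32), walls,
    train_cfg=TrainConfig(roi_epochs=5, frames_per_epoch_roi=256, seed=0))
print(f"\nROI detector parameters : {detector.n_params()}")
print(f"training loss           : {history['train_loss'][0]:.4f} -> "
      f"{history['train_loss'][-1]:.4f}")

centers = detector.predict_centers(env[:200])
truth = walls[:200].mean(axis=1)
print(f"lumen-center MAE        : {np.abs(centers - truth).mean():.2f} samples")

window = lf.clip_roi(env[0], centers[0], window_width=401)
print(f"clipped ROI             : start {window.start}, "
      f"{len(window.values)} samples wide")
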