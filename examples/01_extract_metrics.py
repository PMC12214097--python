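"""Extract minimal vertical acromiohumeral distances from a landmark clip.

Simulates a full-can posture recording with known per-phase minima
(abduction 0.25 cm, adduction 0.32 cm), adds labeling jitter, and runs the
extractor. The printed per-cycle minima and their means should sit within a
few hundredths of a centimeter of the programmed values — the residual is
the labeling noise.
"""
from subacrodyn import TrajectoryParams, extract_mvahd, simulate_trajectory

params = TrajectoryParams(
    target_min_ab=0.25, target_min_ad=0.32, noise_sd=0.02, seed=42
)
clip = simulate_trajectory(params)
result = extract_mvahd(clip)

print(f"clip: {len(clip)} frames at {clip.fps} fps, posture {clip.posture}")
print(result.per_cycle_minima.round(3))
print(f"mVAHD abduction ({result.metric_keys['abduction']}): "
      f"{result.mvahd_ab:.3f} cm (programmed 0.25)")
print(f"mVAHD adduction ({result.metric_keys['adduction']}): "
      f"{result.mvahd_ad:.3f} cm (programmed 0.32)")
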