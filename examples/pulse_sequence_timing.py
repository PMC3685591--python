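"""First-order skin response and the valid analysis time window.

Skin heated by a laser pulse behaves like a first-order inertia system:
T(t) = T0 + dT (1 - exp(-t / tau)).  A frame is only analyzable once the
elevated steady state is reached (about 10 s after the last pulse) and
before thermoregulation blurs the footprints (a few minutes).
"""

import thermocover as tc

scene = tc.SyntheticScene(
    shape=(60, 80),
    pulses=[(30.0, 40.0, 20.0, 0.0)],
    roi_polygon=[(20.0, 30.0), (20.0, 50.0), (40.0, 50.0), (40.0, 30.0)],
    noise_sd_c=0.0,
    tau_s=1.5,
)

times = [0.5, 1.0, 1.5, 3.0, 6.0, 12.0]
frames = tc.generate_sequence(scene, times)
print("time [s]  centre temp [degC]  fraction of full elevation")
for t, frame in zip(times, frames):
    temp = frame.values[30, 40]
    print(f"{t:7.1f}  {temp:18.3f}  {(temp - 33.0) / 2.5:24.3f}")
print(f"\n(tau = {scene.tau_s} s: at t = tau the elevation reaches 1 - 1/e = 0.632)")

print("\nanalysis-window verdicts:")
for t in (5.0, 10.0, 60.0, 300.0):
    verdict = tc.check_analysis_window(t)
    state = "valid" if verdict.valid else "invalid"
    print(f"  t = {t:5.0f} s -> {state:7s} ({verdict.reason})")
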