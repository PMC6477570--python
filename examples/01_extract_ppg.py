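"""Extract a blood-volume pulse from a simulated fingertip camera recording.

Plants a known beat-to-beat interval series, renders 20 s of red-channel
frames whose histogram spread pulses with the heartbeat, and runs the
spatial-entropy extraction pipeline: negated per-frame entropy -> 256 Hz
spline resampling -> 1 s moving-average equalisation -> 0.5 s local-maxima
peak picking.
"""
import numpy as np

from ppgtherm import (
    RRParams,
    cardiac_psqi,
    extract_ppg,
    generate_rr,
    render_ppg_frames,
)

rr = generate_rr(RRParams(mean_rr=850.0, sdpp_target=45.0,
                          rmssd_target=35.0, duration=20.0, seed=7))
stack = render_ppg_frames(rr, seed=8)
print(f"planted {len(rr)} intervals, mean {rr.intervals.mean():.1f} ms")

bvp, pp = extract_ppg(stack)
n = min(len(pp), len(rr))
err = np.abs(pp.intervals[:n] - rr.intervals[:n])
print(f"recovered {len(pp)} intervals ({int(pp.valid.sum())} valid)")
print(f"mean absolute recovery error: {err.mean():.2f} ms "
      f"(one 256 Hz sample = 3.91 ms)")
print(f"cardiac pSQI of the extracted BVP: {cardiac_psqi(bvp):.3f} "
      f"(fraction of power in the 0.8-2.0 Hz heart-rate band; 1 = clean)")
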