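"""Quantify tetanic contraction from a synthetic myotube movie.

Generates a textured movie whose tissue contracts radially by 3 px
during each 1 s stimulation burst (4 s rest), then recovers the
displacement trace with dense optical flow.
"""

import numpy as np

from ochip_loop import ContractionMovieSpec, generate_contraction_movie, trace_displacement

spec = ContractionMovieSpec(
    n_frames=50, frame_rate=5.0, peak_displacement=3.0, frame_shape=(96, 96), seed=0
)
movie, ground_truth = generate_contraction_movie(spec)
trace = trace_displacement(movie, spec.frame_rate)

print(f"frames            : {len(movie)} ({len(movie) / spec.frame_rate:.0f} s at {spec.frame_rate:.0f} fps)")
print(f"true peak         : {ground_truth.peak():.2f} px")
print(f"estimated peak    : {trace.peak():.2f} px")
on = spec.schedule()
pair_on = on[:-1] | on[1:]
print(f"mean |flow| on/off: {trace.mean_magnitude[pair_on].mean():.3f} / "
      f"{trace.mean_magnitude[~pair_on].mean():.5f} px")
# Flow spikes at burst onset and release recover the commanded peak
# displacement within a few percent; between bursts the field is static.
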