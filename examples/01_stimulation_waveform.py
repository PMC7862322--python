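"""Synthesize the tetanus-inducing stimulation signal and verify it.

The default protocol drives skeletal muscle to complete tetanus: 40 Vpp
rectangular pulses at 40 Hz, 4 ms wide, in 1 s bursts with 4 s rest.
"""

from ochip_loop import PulseTrainSpec, count_pulses, measure_pulse_width, synthesize

spec = PulseTrainSpec()  # 40 Vpp, 40 Hz, 4 ms, 1 s burst, 4 s rest
wave = synthesize(spec)

print(f"duration          : {wave.duration:.1f} s (burst + rest)")
print(f"pulses per burst  : {count_pulses(wave)}")
print(f"measured width    : {measure_pulse_width(wave) * 1e3:.1f} ms")
print(f"voltage levels    : {sorted({float(v) for v in wave.voltages})} V")
# 40 pulses of 4 ms in the 1 s burst confirm the pulse-repetition rate;
# the bipolar +-20 V levels realize the 40 V peak-to-peak amplitude.
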