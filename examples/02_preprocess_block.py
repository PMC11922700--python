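"""Preprocess one EEG block: band-pass, average reference, ocular ICA,
jump rejection — and check each step against the generator's ground truth.

The block carries Poisson-placed blinks, saccades and one high-amplitude
jump transient. Blink variance at the frontal-polar channels should
collapse after ICA template rejection, and the jump should be covered by
the 15-SD peak-to-trough rejection mask (with its 0.5 s padding).
"""

import numpy as np

import eegimpact as ei
from eegimpact.simulate import draw_subject_offsets, generate_block, session_blocks

config = ei.CohortConfig(n_subjects=2, block_duration_s=60.0, seed=23)
off = draw_subject_offsets(config, 0)
rec, truth = generate_block(config, "S01", session_blocks("pre")[0], off)
print(f"raw block: {len(truth.blink_onsets)} blinks, "
      f"{len(truth.saccade_onsets)} saccades, {len(truth.jumps)} jumps injected")

clean = ei.preprocess_block(rec, config.montage)
for step in clean.provenance:
    print(" ", step["step"], {k: v for k, v in step.items()
                              if k not in ("step", "removed")})

ica_report = clean.provenance[2]
for comp in ica_report["removed"]:
    print(f"  removed component {comp['component']}: "
          f"|r| = {comp['correlation']} vs {comp['template']} eye template")

# blink suppression at Fp1/Fp2, quantified against ground-truth onsets
filt = ei.rereference_average(ei.bandpass(rec))
fp = [config.montage.index("Fp1"), config.montage.index("Fp2")]
w = int(0.3 * rec.fs)
before = np.mean([filt.data[fp, o:o + w].var() for o in truth.blink_onsets])
after = np.mean([clean.recording.data[fp, o:o + w].var()
                 for o in truth.blink_onsets])
print(f"blink-window variance at Fp1/Fp2: {before:.0f} -> {after:.0f} uV^2 "
      f"({100 * (1 - after / before):.0f}% suppressed)")

print(f"rejection mask: {100 * clean.mask.fraction_excluded:.2f}% of samples, "
      f"intervals (s): {[(round(a, 2), round(b, 2)) for a, b in clean.mask.intervals]}")
for j in truth.jumps:
    covered = clean.mask.excluded[j["start"]:j["start"] + j["n_samples"]].all()
    print(f"  injected jump at sample {j['start']} covered by mask: {covered}")
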