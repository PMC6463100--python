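"""Calibrate and apply the homopolymer indel error filter.

A true indel is supported consistently (every indel-bearing read shows the
same length: var = 0, frmode = 1); a slippage artifact shows a spread of
lengths. Thresholds are taken from the extremes of the true-positive
training indels, so no training TP is ever rejected.
"""

from ampvar import (
    PileupSimConfig,
    VariantKey,
    calibrate,
    compute_frmode,
    compute_var,
    decide,
    extract_event_lengths,
    make_reference,
    simulate_pileup,
    simulate_training_set,
)

reference = make_reference(seed=0)  # 400 bp with a TTTTTTTT run at offset 200
site = VariantKey("chr1", 200, reference[199] + "T", reference[199])

for label, slippage in [("clean true deletion", 0.0), ("noisy artifact-like site", 0.6)]:
    reads = simulate_pileup(
        PileupSimConfig(reference=reference, site_pos=200, true_length=-1,
                        n_reads=40, slippage_prob=slippage, seed=1)
    )
    dist = extract_event_lengths(reads, site)
    print(f"{label}: var={compute_var(dist):.4f} frmode={compute_frmode(dist):.4f} "
          f"({len(dist.lengths)} indel-bearing of {dist.n_covering} covering reads)")

# calibrate on a labeled synthetic cohort (18 TP / 90 FP, like a
# Sanger-validated training set) and apply the any-aligner decision rule
training = simulate_training_set(seed=0)
thresholds = calibrate(training)
print(f"\ncalibrated thresholds: maxVar={thresholds.max_var:.4f} "
      f"minFrmode={thresholds.min_frmode:.4f}")

fp = [t for t in training if t.label == "FP"]
removed = sum(not decide([(t.var, t.frmode)], thresholds).passed for t in fp)
print(f"FP training indels removed: {removed}/{len(fp)}")
print(f"TP training indels removed: 0/18 (guaranteed by threshold construction)")

# the conservative any-aligner rule at the default operating point
# (maxVar = 0.055, minFrmode = 0.9790): one dispersed aligner is enough
from ampvar import HomopolymerThresholds

defaults = HomopolymerThresholds()
stats = [(0.00, 1.00), (0.01, 0.995), (0.10, 0.90)]
print("\nthree aligners, one violating the default thresholds ->",
      "rejected" if not decide(stats, defaults).passed else "retained")
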