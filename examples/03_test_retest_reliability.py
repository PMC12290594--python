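"""Recover a known test-retest reliability from a twin-session cohort.

Simulates 40 subjects recorded twice; each subject's per-template mean
microstate durations carry a known 0.7 share of between-subject
variance, so the true duration ICC is 0.7 by construction.  The full
pipeline (backfitting + metrics + absolute-agreement ICC + permutation
test) should recover a mean duration ICC close to that value.
"""

from msretest import (
    MicrostateTemplates, PairedMetrics, SynthConfig, backfit, metrics,
    pair_reliability, simulate_cohort,
)

TARGET = 0.7
cfg = SynthConfig(n_channels=16, duration_s=180.0, noise_sd_uv=1.0, seed=21)
cohort = simulate_cohort(cfg, n_subjects=40, icc_target=TARGET)
tmpl = MicrostateTemplates(maps=cohort.template_maps, labels=list("ABCD"))

sessions = [[], []]
for s in range(len(cohort.subjects)):
    for j in range(2):
        seq = backfit(cohort.recordings[s][j], tmpl)
        sessions[j].append(metrics(seq, labels=tmpl.labels))

pair = PairedMetrics(subjects=cohort.subjects, session_a=sessions[0],
                     session_b=sessions[1], pairing_label="session1 vs session2")
report = pair_reliability(pair, reps=1000, seed=0)

print(f"true duration ICC by construction: {TARGET}")
for metric in ("duration", "occurrence", "coverage", "transition"):
    print(f"{metric:>10}: mean ICC {report.mean_icc[metric]: .3f} "
          f"({report.category[metric]}, permutation p = {report.p_perm[metric]:.4g})")
print("\nduration/occurrence track the planted subject effect; transition")
print("probabilities carry no subject-level signal here, so their ICC is low.")
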