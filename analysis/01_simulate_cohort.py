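"""Simulate the reference synthetic cohort.

Generates 27 spread-gating (PEIRS) agents at the documented default
parameters on the standard session (4 blocks x 120 trials, every ordered
stimulus pair 10x per block) and writes the trial table plus the
ground-truth manifest under results/cohort_peirs/.
"""

from pathlib import Path

from riskbandit.cohort import CohortSpec, generate_cohort, save_cohort

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort_peirs"
SEED = 11


def main() -> None:
    spec = CohortSpec(
        "PEIRS", n_participants=27, parameter_source="defaults", seed=SEED
    )
    cohort = generate_cohort(spec)
    save_cohort(cohort, OUT)
    n_trials = sum(m.session.n_trials for m in cohort)
    print(f"simulated {len(cohort)} PEIRS agents, {n_trials} trials total")
    print(f"ground truth: {cohort[0].parameters}")
    print(f"wrote {OUT}/trials.csv and manifest.json")


if __name__ == "__main__":
    main()
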