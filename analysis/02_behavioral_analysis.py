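"""Behavioural battery on the reference cohort.

Applies the inclusion filter, computes the binned accuracy trace, the
condition-specific risk preferences with their t-tests, and the
emergence-speed test (do value preferences grow faster than risk
preferences?).  Reads results/cohort_peirs/ from 01_simulate_cohort.py.
"""

import json
from pathlib import Path

from riskbandit.behavior import analyze_cohort
from riskbandit.task import read_sessions

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sessions = read_sessions(ROOT / "cohort_peirs" / "trials.csv")
    report = analyze_cohort(sessions)
    print(
        f"included {len(report.included_ids)}/{report.n_total} participants "
        f"(excluded: {report.excluded_ids or 'none'})"
    )
    tests = report.tests
    for name in ("both_high_vs_both_low", "both_high_vs_chance", "both_low_vs_chance"):
        r = tests[name]
        print(f"{name}: t({r['df']}) = {r['t']:.2f}, p = {r['p']:.4g}")
    print(f"mean condition difference: {tests['mean_difference']['value']:.3f}")
    em = report.emergence
    print(
        f"emergence: value slope {em['mean_value_slope']:.4f} vs risk slope "
        f"{em['mean_risk_slope']:.4f}, t({em['df']}) = {em['t']:.2f}, "
        f"p = {em['p']:.4g}"
    )
    report.accuracy.to_csv(ROOT / "accuracy_trace.csv", index=False)
    report.risk_summaries.to_csv(ROOT / "risk_summaries.csv", index=False)
    (ROOT / "behavior_report.json").write_text(
        json.dumps({"tests": tests, "emergence": em}, indent=2)
    )
    print(f"wrote {ROOT}/accuracy_trace.csv, risk_summaries.csv, behavior_report.json")


if __name__ == "__main__":
    main()
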