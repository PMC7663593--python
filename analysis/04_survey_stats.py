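"""Survey statistics and the biomarker-vs-survey correlation.

Summarises the self-perceived stress level (SPSL) per group and instant,
runs the within-group phase contrasts and between-group comparisons with
the exact Wilcoxon signed-rank test (Lilliefors normality gate reported),
and correlates the group-mean SPSL with the group-mean relative gamma at
the four survey instants.
"""

import json
from pathlib import Path

import rgstress as rg
from rgstress.io import load_surveys
from rgstress.surveys import records_from_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 0


def main() -> None:
    surveys_path = RESULTS / "surveys.csv"
    if not surveys_path.exists():
        cohort = rg.default_cohort(n_subjects=20, seed=SEED)
        rg.generate_spsl(cohort, seed=SEED).to_csv(surveys_path, index=False)
    df = load_surveys(surveys_path)
    summary = rg.summarize_spsl(records_from_frame(df), lilliefors_seed=SEED)

    print("SPSL means (1-5 scale):")
    print(summary.means.round(2).to_string())
    print("\nwithin-group phase contrasts (exact Wilcoxon signed-rank):")
    out = {"within": {}, "between": {}}
    for (g, c), t in summary.within_group.items():
        star = " *" if t.significant else ""
        print(f"  {g:8s} {c}: p = {t.p_value:.4f}{star}  (n = {t.n}; {t.notes or 'no zeros'})")
        out["within"][f"{g}:{c}"] = t.p_value
    print("\nbetween-group comparisons at each instant:")
    for inst, t in summary.between_group.items():
        star = " *" if t.significant else ""
        print(f"  {inst}: p = {t.p_value:.4f}{star}")
        out["between"][inst] = t.p_value
    print("\n(the stressor raises SPSL and relaxation lowers it within both"
          " groups, while the two relaxation media do not differ; no"
          " multiple-testing correction applied)")

    report_path = RESULTS / "pipeline" / "report.json"
    if report_path.exists():
        payload = json.loads(report_path.read_text())
        print("\nSPSL vs relative gamma at T1-T4 (group means):")
        for g, r in payload["spsl_rg_correlation"].items():
            print(f"  {g}: PCC = {r:.2f}")
        out["spsl_rg"] = payload["spsl_rg_correlation"]

    (RESULTS / "survey_stats.json").write_text(json.dumps(out, indent=2,
                                                          sort_keys=True))
    print(f"\nwrote survey_stats.json to {RESULTS}")


if __name__ == "__main__":
    main()
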