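"""Baseline characteristics of the primary-suspect cohort: counts and
percentages by sex, age band, weight band, reporter, worst outcome,
country and indication, missingness shown as its own level."""

from pvsignal.demographics import summarize_demographics

from _common import RESULTS, universe


def main() -> None:
    _, cohort, _ = universe()
    table = summarize_demographics(cohort)
    table.to_csv(RESULTS / "demographics.csv", index=False)
    print(f"cohort: {cohort.n_reports} reports")
    for cat in ("sex", "age_years", "outcome"):
        sub = table[table["category"] == cat]
        desc = ", ".join(f"{r.level} {r.percent}%" for r in sub.itertuples())
        print(f"  {cat}: {desc}")
    print(f"wrote {RESULTS / 'demographics.csv'}")


if __name__ == "__main__":
    main()
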