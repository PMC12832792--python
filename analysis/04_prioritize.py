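"""Clinical priority scoring of the signals flagged by all four
algorithms: reporting rate, stability across three designated analyses,
case fatality and DME/IME membership, banded low / moderate / high."""

from _common import CONFIG, RESULTS, universe
from pvsignal.priority import prioritize_signals
from pvsignal.signals import evaluate_signals


def main() -> None:
    store, _, _ = universe()
    frame = evaluate_signals(store, CONFIG.target_drug)
    prio = prioritize_signals(frame, store, criterion="positive_all")
    prio.to_csv(RESULTS / "priority.csv", index=False)
    print(f"prioritized {len(prio)} all-four-positive signals")
    for r in prio.itertuples():
        print(f"  {r.event}: rate {100 * r.reporting_rate:.1f}% ({r.rate_score}) "
              f"stability {r.stability_count}/3 ({r.stability_score}) "
              f"fatality {100 * r.fatality_rate:.1f}% ({r.fatality_score}) "
              f"DME/IME {r.dme_ime_score} -> total {r.total} [{r.priority_class}]")
    print(f"wrote {RESULTS / 'priority.csv'}")


if __name__ == "__main__":
    main()
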