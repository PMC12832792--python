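"""Four-algorithm disproportionality screen (ROR, PRR+chi2, BCPNN IC,
MGPS EBGM) of the focal drug at PT and SOC level, plus the sex- and
age-stratified re-screens, with forest-plot-ready output."""

from _common import CONFIG, RESULTS, universe
from pvsignal.signals import evaluate_signals, forest_frame, subgroup_screen


def main() -> None:
    store, _, truth = universe()
    drug = CONFIG.target_drug

    for level in ("PT", "SOC"):
        frame = evaluate_signals(store, drug, level)
        frame.to_csv(RESULTS / f"signals_{level.lower()}.csv", index=False)
        forest_frame(frame).to_csv(RESULTS / f"forest_{level.lower()}.csv", index=False)
        pos = frame[frame["positive_all"]]
        print(f"{level} screen: {len(frame)} events, {int(frame['positive_any'].sum())} "
              f"positive by >=1 algorithm, {len(pos)} by all four")
        for r in pos.head(5).itertuples():
            print(f"   {r.event}: a={r.a} ROR {r.ror:.2f} ({r.ror_lo:.2f}-{r.ror_hi:.2f}) "
                  f"EBGM {r.ebgm:.2f} (EB05 {r.ebgm05:.2f}) IC025 {r.ic025:.2f}")
    print("planted ground truth:", truth.planted_rr)

    for stratifier in ("sex", "age_bins"):
        sg = subgroup_screen(store, stratifier, drug, criterion="positive_any")
        for name, frame in sg.per_stratum.items():
            safe = name.replace("<", "lt").replace(">=", "ge")
            frame[frame["positive_any"]].to_csv(
                RESULTS / f"subgroup_{stratifier}_{safe}.csv", index=False)
        excl_counts = {k: len(v) for k, v in sg.exclusive.items()}
        print(f"{stratifier} subgroups: {len(sg.shared)} shared positives, "
              f"exclusives per stratum {excl_counts}")


if __name__ == "__main__":
    main()
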