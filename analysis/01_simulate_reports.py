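"""Generate the synthetic spontaneous-report universe and record what was
planted.

Emits the ground truth (planted relative risks, onset law, demographic
logit coefficients) to results/ground_truth.json and the raw quarterly
dialect files to scratch/faers/ for inspection; downstream scripts
regenerate the same universe from the shared seed."""

import json

from pvsignal.faers_io import write_faers_dialect

from _common import CONFIG, RESULTS, universe


def main() -> None:
    store, cohort, truth = universe()
    print(f"universe: {store.n_reports} deduplicated reports, "
          f"{store.reactions['pt'].nunique()} distinct PTs")
    print(f"primary-suspect cohort ({CONFIG.target_drug}): {cohort.n_reports} reports")
    print("planted relative risks:", truth.planted_rr)
    print(f"onset law: Weibull(shape {truth.tto_shape}, scale {truth.tto_scale} days)")

    out = {
        "seed": CONFIG.seed,
        "n_reports": store.n_reports,
        "cohort_reports": cohort.n_reports,
        "planted_rr": {f"{d}|{e}": rr for (d, e), rr in truth.planted_rr.items()},
        "tto": {"shape": truth.tto_shape, "scale": truth.tto_scale},
        "covariate_effects": truth.covariate_effects,
        "target_event": truth.target_event,
    }
    (RESULTS / "ground_truth.json").write_text(json.dumps(out, indent=1))

    scratch = RESULTS.parent / "scratch" / "faers"
    write_faers_dialect(store, scratch)
    print(f"wrote ground truth to {RESULTS / 'ground_truth.json'} and "
          f"dialect files to {scratch}")


if __name__ == "__main__":
    main()
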