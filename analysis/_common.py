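"""Shared setup for the numbered analysis scripts: one seeded synthetic
universe emulating the regorafenib pharmacovigilance cohort, cleaned the
same way in every script so each stays independently runnable."""

from pathlib import Path

from pvsignal.cleaning import deduplicate, filter_primary_suspect
from pvsignal.synth import SyntheticConfig, generate

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"

CONFIG = SyntheticConfig(n_reports=50_000, seed=SEED)


def universe():
    """(full deduplicated store, primary-suspect cohort, ground truth)."""
    store, truth = generate(CONFIG)
    store = deduplicate(store)
    cohort = filter_primary_suspect(store, [CONFIG.target_drug])
    RESULTS.mkdir(exist_ok=True)
    return store, cohort, truth
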