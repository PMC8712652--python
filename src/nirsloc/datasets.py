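"""Bundled reference datasets.

Two small benchmark tables from the 25-subject normal-hearing
sound-localization study this analysis chain replicates:

* per-subject best LOOCV decoding accuracies (percent) for the six
  lateral/front contrasts and the six +/-30 deg contrasts at both levels;
* per-subject behavioral RMS localization errors (degrees) at 48 dB, 58 dB
  and pooled.

They serve as inputs to the summary operations (group means, >=70% counts,
pooling-identity checks), not as fitted quantities.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_accuracies", "load_reference_rms", "SUBJECTS"]

SUBJECTS: tuple[str, ...] = tuple(f"S{i}" for i in range(1, 26))


def _read(name: str) -> pd.DataFrame:
    with resources.files("nirsloc.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_reference_accuracies() -> pd.DataFrame:
    """Long-form accuracies: block, intensity_db, pair, subject, accuracy_pct."""
    wide = _read("reference_accuracies.csv")
    long = wide.melt(
        id_vars=["block", "intensity_db", "pair"],
        value_vars=list(SUBJECTS),
        var_name="subject",
        value_name="accuracy_pct",
    )
    return long


def reference_accuracy_row(intensity_db: int, pair: str) -> dict[str, float]:
    """One contrast's per-subject accuracies as {subject: fraction in [0,1]}."""
    df = load_reference_accuracies()
    sel = df[(df.intensity_db == intensity_db) & (df.pair == pair)]
    if sel.empty:
        raise KeyError(f"no reference row for {pair} at {intensity_db} dB")
    return {r.subject: r.accuracy_pct / 100.0 for r in sel.itertuples()}


def load_reference_rms() -> pd.DataFrame:
    """Per-subject RMS localization errors (degrees): low/high/pooled."""
    return _read("reference_rms.csv")
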