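"""Map samples to regions using the father's-birthplace-first rule.

A sample's geographic origin is its father's birth region when recorded
(one generation further back, limiting the effect of recent internal
migration), otherwise its own birth region.  Samples with no birthplace at
all, a foreign birthplace, or a birthplace in an excluded region are removed
with their reason recorded in an accounting ledger.
"""

from __future__ import annotations

import pandas as pd

from .geography import RegionVocabulary, default_vocabulary

__all__ = ["assign_regions"]

_EXCLUSIONS = ("missing_geo", "foreign", "excluded_region")


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or v == ""


def assign_regions(
    metadata: pd.DataFrame,
    vocab: RegionVocabulary | None = None,
    excluded_regions: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assign each sample a region or an exclusion reason.

    Parameters
    ----------
    metadata : DataFrame
        Must have ``sample_id``, ``own_region`` and ``father_region``
        columns (the birthplace columns nullable).
    vocab : RegionVocabulary, optional
        Region vocabulary; the bundled 19-region default when omitted.
    excluded_regions : list of str, optional
        Recognised codes excluded from the analyses; defaults to the
        vocabulary's ``excluded_by_default`` (the low-coverage island
        region).

    Returns
    -------
    assignments : DataFrame
        sample_id, region (or None), reason (None when retained),
        provenance in {"father", "self", None}.
    ledger : dict
        input, father_mapped, self_mapped, missing_geo, foreign,
        excluded_region, retained.  Retained + the three exclusions equals
        the input count; father + self mapped equals retained + foreign +
        excluded_region (those have a birthplace but are excluded for other
        reasons).
    """
    vocab = vocab or default_vocabulary()
    if excluded_regions is None:
        excluded_regions = list(vocab.excluded_by_default)
    excluded = set(excluded_regions)
    recognized = vocab.recognized_codes | excluded

    bad = []
    for _, row in metadata.iterrows():
        for col in ("own_region", "father_region"):
            v = row[col]
            if not _is_missing(v) and v not in recognized:
                bad.append((row["sample_id"], col, v))
    if bad:
        raise ValueError(f"unrecognized region codes: {bad[:10]}"
                         + (" ..." if len(bad) > 10 else ""))

    records = []
    ledger = dict(input=len(metadata), father_mapped=0, self_mapped=0,
                  missing_geo=0, foreign=0, excluded_region=0, retained=0)
    for _, row in metadata.iterrows():
        father, own = row["father_region"], row["own_region"]
        if not _is_missing(father):
            birth, provenance = father, "father"
        elif not _is_missing(own):
            birth, provenance = own, "self"
        else:
            records.append((row["sample_id"], None, "missing_geo", None))
            ledger["missing_geo"] += 1
            continue
        ledger[f"{provenance}_mapped"] += 1
        if birth == vocab.foreign_code:
            records.append((row["sample_id"], None, "foreign", provenance))
            ledger["foreign"] += 1
        elif birth in excluded:
            records.append((row["sample_id"], None, "excluded_region", provenance))
            ledger["excluded_region"] += 1
        else:
            records.append((row["sample_id"], birth, None, provenance))
            ledger["retained"] += 1
    assignments = pd.DataFrame(
        records, columns=["sample_id", "region", "reason", "provenance"]
    )
    return assignments, ledger
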