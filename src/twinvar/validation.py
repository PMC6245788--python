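"""Re-examination of candidate outlier probes in concordant and healthy pairs.

A variance hit in the discordant pairs could reflect a technical artifact or
a genetically driven methylation level rather than a disease-linked
epimutation.  The check: at each candidate probe, profile every validation
pair (concordant and healthy) and classify its pattern.

* ``discordant_outlier`` — exactly one co-twin is extreme relative to the
  rest of the cohort: the same single-co-twin pattern the scan detects, so
  seeing it in a validation pair argues the candidate is not disease-bound.
* ``shared_outlier`` — both co-twins are extreme *and* nearly identical
  (within a few percentage points): the signature of a sequence variant or a
  shared exposure, not of a stochastic epimutation.  It is reported but does
  not invalidate a candidate.
* ``normative`` — everything else.

"Extreme" is operationalised as a robust z-score (median / scaled MAD of
the out-of-pair samples) beyond a threshold, default 3.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet, ValueRangeError

logger = logging.getLogger(__name__)

__all__ = ["profile_pairs", "classify_pair_pattern", "validate_candidates"]

PATTERNS = ("normative", "shared_outlier", "discordant_outlier")
MAD_SCALE = 1.4826  # makes the MAD consistent with the s.d. under normality


def classify_pair_pattern(
    value_a: float,
    value_b: float,
    reference_values,
    z_threshold: float = 3.0,
    shared_diff_threshold_pp: float = 5.0,
) -> str:
    """Classify one pair's methylation pattern at one probe.

    A co-twin is "outlying" when its robust z-score against
    ``reference_values`` (all out-of-pair samples at this probe) exceeds
    ``z_threshold`` in absolute value.  Both co-twins outlying with an
    intrapair difference under ``shared_diff_threshold_pp`` percentage
    points -> ``shared_outlier``; exactly one outlying ->
    ``discordant_outlier``; otherwise ``normative``.

    When the reference has zero spread (scaled MAD of 0) the rule falls back
    to distance beyond the reference range.
    """
    ref = np.asarray(reference_values, dtype=float)
    ref = ref[~np.isnan(ref)]
    if ref.size < 4:
        raise ValueRangeError("need at least 4 reference values to classify a pair")
    center = np.median(ref)
    spread = MAD_SCALE * np.median(np.abs(ref - center))
    if spread > 0:
        out_a = abs(value_a - center) / spread > z_threshold
        out_b = abs(value_b - center) / spread > z_threshold
    else:
        margin = shared_diff_threshold_pp / 100.0
        lo, hi = ref.min(), ref.max()
        logger.info("zero reference MAD; falling back to range rule")
        out_a = value_a < lo - margin or value_a > hi + margin
        out_b = value_b < lo - margin or value_b > hi + margin

    diff_pp = abs(value_a - value_b) * 100.0
    if out_a and out_b and diff_pp < shared_diff_threshold_pp:
        return "shared_outlier"
    if out_a != out_b:
        return "discordant_outlier"
    return "normative"


def profile_pairs(
    beta: BetaMatrix,
    sheet: SampleSheet,
    probes,
    pair_classes=("concordant", "healthy"),
    z_threshold: float = 3.0,
    shared_diff_threshold_pp: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile candidate probes in the pairs of the requested classes.

    Returns ``(profiles, tidy)``: one classified row per (probe, pair), and
    a tidy sample-level table (probe, pair, sample, role, status, beta)
    suitable for per-pair line plots.  The classification reference for a
    pair is every sample in ``beta`` outside that pair.
    """
    probes = list(probes)
    missing = [p for p in probes if p not in beta.probe_ids]
    if missing:
        raise KeyError(f"probes absent from beta matrix: {missing[:5]}")
    meta = sheet.table.set_index("sample_id")

    pair_ids = [pid for cls in pair_classes for pid in sheet.pairs_of_class(cls)]
    rows, tidy_rows = [], []
    for probe in probes:
        values = beta.values.loc[probe]
        for pair_id in pair_ids:
            members = sheet.table[sheet.table["pair_id"] == pair_id]
            members = members.sort_values("role")  # twin_a then twin_b
            ids = members["sample_id"].tolist()
            va, vb = (float(values[s]) for s in ids)
            ref = values.drop(labels=ids).to_numpy(dtype=float)
            pattern = classify_pair_pattern(
                va, vb, ref, z_threshold=z_threshold,
                shared_diff_threshold_pp=shared_diff_threshold_pp,
            )
            rows.append(
                {
                    "probe_id": probe,
                    "pair_id": pair_id,
                    "pair_class": members["pair_class"].iloc[0],
                    "value_a": va,
                    "value_b": vb,
                    "intrapair_diff_pp": abs(va - vb) * 100.0,
                    "pattern": pattern,
                }
            )
            for s in ids:
                tidy_rows.append(
                    {
                        "probe_id": probe,
                        "pair_id": pair_id,
                        "sample_id": s,
                        "role": meta.loc[s, "role"],
                        "status": meta.loc[s, "status"],
                        "pair_class": meta.loc[s, "pair_class"],
                        "beta": float(values[s]),
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(tidy_rows)


def validate_candidates(candidates, profiles: pd.DataFrame) -> pd.DataFrame:
    """Summarise validation-pair patterns per candidate probe.

    ``candidates`` is an iterable of probe ids (or a scan stats frame, in
    which case its flagged outliers are used).  A candidate is *validated*
    when no validation pair shows a ``discordant_outlier`` pattern at it;
    ``shared_outlier`` pairs are counted and annotated as SNV-suspect but do
    not invalidate.
    """
    if isinstance(candidates, pd.DataFrame):
        candidates = candidates.loc[candidates["outlier"], "probe_id"].tolist()
    candidates = list(candidates)
    missing = sorted(set(candidates) - set(profiles["probe_id"]))
    if missing:
        raise KeyError(f"no profiles computed for candidates: {missing[:5]}")

    rows = []
    for probe in candidates:
        sub = profiles[profiles["probe_id"] == probe]
        counts = sub["pattern"].value_counts()
        n_disc = int(counts.get("discordant_outlier", 0))
        n_shared = int(counts.get("shared_outlier", 0))
        rows.append(
            {
                "probe_id": probe,
                "n_validation_pairs": len(sub),
                "n_normative": int(counts.get("normative", 0)),
                "n_shared_outlier": n_shared,
                "n_discordant_outlier": n_disc,
                "validated": n_disc == 0,
                "snv_suspect": n_shared > 0,
                "offending_pairs": ",".join(
                    sub.loc[sub["pattern"] == "discordant_outlier", "pair_id"].astype(str)
                ),
            }
        )
    return pd.DataFrame(rows)
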