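"""Confidence-score strength analysis against human rater agreement.

The strength of a classifier's conviction is |CS - 0.5| in [0, 0.5],
binned into thirds: unconfident (< 1/6), moderately confident
([1/6, 1/3)) and confident (>= 1/3).  Eyes are independently stratified
by how many of three raters match the supervised label (3/2/1/0 ->
agreement / partial agreement / partial disagreement / disagreement),
and the bin composition of each stratum is cross-tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CONFIDENCE_BINS = ("unconfident", "moderately_confident", "confident")
AGREEMENT_GROUPS = (
    "agreement",
    "partial_agreement",
    "partial_disagreement",
    "disagreement",
)
_GROUP_BY_MATCHES = {3: "agreement", 2: "partial_agreement",
                     1: "partial_disagreement", 0: "disagreement"}


@dataclass(frozen=True)
class ConfidenceRecord:
    eye_id: str
    cs: float
    strength: float
    bin: str


@dataclass(frozen=True)
class AgreementRecord:
    eye_id: str
    supervised_label: str
    rater_labels: tuple[str, str, str]
    n_match: int
    group: str


def confidence_bin(cs: float) -> str:
    """Bin a confidence score by strength |cs - 0.5| (thirds of [0, 0.5])."""
    if not 0.0 <= cs <= 1.0:
        raise ValueError(f"cs must be in [0, 1], got {cs}")
    s = abs(cs - 0.5)
    if s < 1.0 / 6.0:
        return "unconfident"
    if s < 1.0 / 3.0:
        return "moderately_confident"
    return "confident"


def confidence_record(eye_id: str, cs: float) -> ConfidenceRecord:
    return ConfidenceRecord(eye_id, cs, abs(cs - 0.5), confidence_bin(cs))


def agreement_group(
    supervised: str, raters: Sequence[str], eye_id: str = ""
) -> AgreementRecord:
    """Stratify one eye by rater-vs-supervised match count."""
    if len(raters) != 3:
        raise ValueError(f"expected exactly 3 rater labels, got {len(raters)}")
    valid = {"symmetric", "asymmetric"}
    if supervised not in valid or any(r not in valid for r in raters):
        raise ValueError("labels must be 'symmetric' or 'asymmetric'")
    n_match = sum(r == supervised for r in raters)
    return AgreementRecord(
        eye_id, supervised, tuple(raters), n_match, _GROUP_BY_MATCHES[n_match]
    )


def crosstab(
    conf: Sequence[ConfidenceRecord], agr: Sequence[AgreementRecord]
) -> pd.DataFrame:
    """Per-agreement-group percentage of eyes in each confidence bin.

    Rows = agreement groups present in the joined data (plus their eye
    counts and share of all eyes); bin percentages sum to 100 per row.
    """
    cs_by_id = {c.eye_id: c for c in conf}
    joined = [(a, cs_by_id[a.eye_id]) for a in agr if a.eye_id in cs_by_id]
    if not joined:
        raise ValueError("no eyes joined between confidence and agreement records")
    rows = []
    total = len(joined)
    for group in AGREEMENT_GROUPS:
        members = [c for a, c in joined if a.group == group]
        if not members:
            continue
        n = len(members)
        row = {"group": group, "n": n, "group_pct": 100.0 * n / total}
        for b in CONFIDENCE_BINS:
            row[b] = 100.0 * sum(c.bin == b for c in members) / n
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def simulate_raters(
    true_labels: Sequence[str],
    per_rater_error: Sequence[float],
    seed: int = 0,
) -> list[tuple[str, str, str]]:
    """Three independent simulated raters flipping labels at given rates.

    Stands in for clinical raters: rater ``j`` reports the supervised
    label flipped independently with probability ``per_rater_error[j]``.
    """
    errs = list(per_rater_error)
    if len(errs) != 3:
        raise ValueError("need exactly 3 rater error probabilities")
    if any(not 0.0 <= e <= 0.5 for e in errs):
        raise ValueError("rater error probabilities must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    flip = {"symmetric": "asymmetric", "asymmetric": "symmetric"}
    out = []
    for lab in true_labels:
        out.append(
            tuple(flip[lab] if rng.random() < e else lab for e in errs)
        )
    return out
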