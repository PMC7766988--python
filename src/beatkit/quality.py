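"""Five-code signal-quality / morphology labelling of fixed epochs, with
multi-annotator adjudication.

Each fixed-length signal chunk (10 s by default) receives one code 0–4,
the product of a two-fold judgement: quality Q0 (bad — reliable HR not
computable), Q1 (acceptable — ≥80% of QRS identifiable) or Q2 (good — HRV
analysis possible), and morphology M0/M1 (P and T waves discernible or
not).  Q0 carries no morphology score.  Recordings are labelled by at
least three annotators; disagreements go to a fourth reviewer and, failing
a 3-to-1 majority, to the whole group.
"""

from __future__ import annotations

import math

from .model import EpochGrid, Track

__all__ = ["encode_label", "decode_label", "adjudicate", "segment_epochs",
           "QUALITY_CODES", "DEFAULT_EPOCH_LENGTH"]

DEFAULT_EPOCH_LENGTH = 10.0  # seconds

# code <-> (quality, morphology); Q0 takes no morphology
QUALITY_CODES = {
    0: ("Q0", None),
    1: ("Q1", "M0"),
    2: ("Q1", "M1"),
    3: ("Q2", "M0"),
    4: ("Q2", "M1"),
}
_REVERSE = {v: k for k, v in QUALITY_CODES.items()}


def encode_label(quality: str, morphology: str | None = None) -> int:
    """Map a (quality, morphology) pair to its integer code 0–4."""
    key = (quality, morphology)
    if key not in _REVERSE:
        raise ValueError(f"invalid label combination {key}")
    return _REVERSE[key]


def decode_label(code: int) -> tuple[str, str | None]:
    """Inverse of :func:`encode_label`."""
    if code not in QUALITY_CODES:
        raise ValueError(f"invalid label code {code} (expected 0-4)")
    return QUALITY_CODES[code]


def adjudicate(votes: list[int], fourth_vote: int | None = None,
               require_unanimous: bool = True) -> tuple[int | None, str]:
    """Resolve annotator votes for one epoch.

    The first three votes decide: agreement yields ``(label,
    "consensus")``.  On disagreement the fourth reviewer's vote is
    consulted (either as ``fourth_vote`` or as a fourth element of
    ``votes``); a 3-to-1 majority yields ``(label, "fourth-review")``,
    anything else ``(None, "group-escalation")``.  If the fourth vote is
    needed but not supplied, ``(None, "fourth-review")`` asks for it.

    With ``require_unanimous=True`` (default) any non-unanimity among the
    first three triggers fourth review; the looser reading
    (``False``) accepts a 2-of-3 majority as consensus.
    """
    votes = [int(v) for v in votes]
    if len(votes) < 3:
        raise ValueError("adjudication requires at least three votes")
    for v in votes + ([int(fourth_vote)] if fourth_vote is not None else []):
        decode_label(v)  # validates range
    first3, extra = votes[:3], votes[3:]
    if fourth_vote is None and extra:
        fourth_vote = extra[0]

    if len(set(first3)) == 1:
        return first3[0], "consensus"
    if not require_unanimous:
        for v in set(first3):
            if first3.count(v) >= 2:
                return v, "consensus"
    if fourth_vote is None:
        return None, "fourth-review"
    all4 = first3 + [int(fourth_vote)]
    for v in set(all4):
        if all4.count(v) >= 3:
            return v, "fourth-review"
    return None, "group-escalation"


def segment_epochs(track: Track, epoch_length: float = DEFAULT_EPOCH_LENGTH,
                   label_set: list[str] | None = None) -> EpochGrid:
    """Cover a track with consecutive fixed-length windows.

    Returns ceil(duration / epoch_length) unlabelled epochs; the trailing
    partial window (if any) is still labelable.  The default label set is
    the five codes "0".."4".
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    n = max(1, math.ceil(track.duration / epoch_length - 1e-12))
    labels = label_set if label_set is not None else [str(c) for c in QUALITY_CODES]
    return EpochGrid(epoch_length, labels, n)
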