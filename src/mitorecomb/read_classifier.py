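"""Per-read conformation support calls and recombination-frequency arithmetic.

A read supports a conformation when it spans the entire repeat plus at least
``min_anchor`` bp of flank on both sides, within the allowed alignment error
rate.  Because all four references share the repeat, the decision reduces to
which upstream/downstream flank anchors the read carries next to the repeat:
the repeat is located once per read (k-mer diagonal voting plus banded edit
distance), then the four anchor combinations are scored and the margin rule
applied.  Ambiguous and unclassified reads are excluded from the frequency
denominator, which reproduces the printed percentage columns exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Mapping, NamedTuple

import numpy as np

from ._kernels import BIG, classify_core, encode, kmer_codes, rolling_vote
from .errors import NoSupportError, ParameterError
from .genome_model import Read
from .conformation_builder import ConformationReference

__all__ = [
    "ClassLabel",
    "ClassificationParams",
    "ReadSupportCounts",
    "Frequencies",
    "PairClassifier",
    "classify_read",
    "count_support",
    "compute_frequencies",
]

_SEED_K = 13
_MIN_SEED_VOTES = 3


class ClassLabel(str, Enum):
    MAJOR1 = "major1"
    MAJOR2 = "major2"
    ALT1 = "alt1"
    ALT2 = "alt2"
    AMBIGUOUS = "ambiguous"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class ClassificationParams:
    min_anchor: int = 100
    max_error_rate: float = 0.15
    min_identity_margin: float = 0.02

    def __post_init__(self) -> None:
        if self.min_anchor < 1:
            raise ParameterError("min_anchor must be >= 1")
        if not 0 < self.max_error_rate < 0.5:
            raise ParameterError("max_error_rate must be in (0, 0.5)")
        if self.min_identity_margin < 0:
            raise ParameterError("min_identity_margin must be >= 0")


@dataclass
class ReadSupportCounts:
    pair_id: str
    m1: int = 0
    m2: int = 0
    a1: int = 0
    a2: int = 0
    ambiguous: int = 0
    unclassified: int = 0

    @property
    def classified_total(self) -> int:
        return self.m1 + self.m2 + self.a1 + self.a2

    @property
    def total(self) -> int:
        return self.classified_total + self.ambiguous + self.unclassified


class Frequencies(NamedTuple):
    major: float
    alternative: float


def _ratio_round(num: int, den: int, places: int = 4) -> float:
    q = Decimal(num) / Decimal(den)
    return float(q.quantize(Decimal(1).scaleb(-places), rounding=ROUND_HALF_UP))


def compute_frequencies(counts: ReadSupportCounts) -> Frequencies:
    """Major/alternative fractions of the classified reads, rounded half-up
    to 4 decimals (the printed-table formatting).

    ``alternative = (a1 + a2) / (m1 + m2 + a1 + a2)``; ambiguous and
    unclassified reads are excluded from the denominator.
    """
    den = counts.classified_total
    if den < 1:
        raise NoSupportError(
            f"pair {counts.pair_id!r}: no classified reads, frequency undefined"
        )
    alt = counts.a1 + counts.a2
    return Frequencies(
        major=_ratio_round(den - alt, den),
        alternative=_ratio_round(alt, den),
    )


class PairClassifier:
    """Precomputed classification state for one repeat pair.

    Build once per pair (via :func:`count_support`) and call
    :meth:`classify` per read.
    """

    def __init__(
        self,
        refs: Mapping[str, ConformationReference],
        params: ClassificationParams | None = None,
    ) -> None:
        self.params = params or ClassificationParams()
        missing = {"major1", "major2", "alt1", "alt2"} - set(refs)
        if missing:
            raise ParameterError(f"missing conformation references: {sorted(missing)}")
        pair_ids = {r.pair_id for r in refs.values()}
        if len(pair_ids) != 1:
            raise ParameterError(f"references from multiple pairs: {sorted(pair_ids)}")
        self.pair_id = next(iter(pair_ids))
        self.refs = dict(refs)

        repeat = refs["major1"].repeat_seq
        self._rep = encode(repeat)
        self._rep_len = len(repeat)

        A = self.params.min_anchor
        m1, m2 = refs["major1"], refs["major2"]

        def up_anchor(r: ConformationReference) -> np.ndarray:
            lo = r.repeat_span[0] - 1
            return encode(r.seq[max(0, lo - A) : lo])

        def dn_anchor(r: ConformationReference) -> np.ndarray:
            hi = r.repeat_span[1]
            return encode(r.seq[hi : hi + A])

        self._up = {1: up_anchor(m1), 2: up_anchor(m2)}
        self._dn = {1: dn_anchor(m1), 2: dn_anchor(m2)}
        self._combos = {
            ClassLabel.MAJOR1: (1, 1),
            ClassLabel.MAJOR2: (2, 2),
            ClassLabel.ALT1: (1, 2),
            ClassLabel.ALT2: (2, 1),
        }

        # sorted k-mer codes of the repeat for diagonal voting
        codes = kmer_codes(self._rep, _SEED_K)
        pos = np.arange(codes.shape[0])
        ok = codes >= 0
        order = np.argsort(codes[ok], kind="stable")
        self._seed_codes = codes[ok][order]
        self._seed_pos = pos[ok][order].astype(np.int64)

        self._band_slack = 16 + self._rep_len // 60
        self._err_budget = self.params.max_error_rate * (self._rep_len + 2 * A)

    # -- internals ---------------------------------------------------------

    def _classify_oriented(self, read_enc: np.ndarray) -> tuple[str, dict] | None:
        diags = rolling_vote(read_enc, _SEED_K, self._seed_codes, self._seed_pos)
        if diags.shape[0] < min(_MIN_SEED_VOTES, max(1, self._rep_len - _SEED_K)):
            return None
        med = np.median(diags)
        near = diags[np.abs(diags - med) <= 0.15 * self._rep_len + 30]
        if near.shape[0] == 0:
            return None
        slack = self._band_slack
        dlo, dhi = int(near.min() - slack), int(near.max() + slack)
        A = self.params.min_anchor
        pad = 12 + A // 8
        err_rep, js, je, eu1, eu2, ed1, ed2 = classify_core(
            read_enc, self._rep,
            self._up[1], self._up[2], self._dn[1], self._dn[2],
            np.int64(dlo), np.int64(dhi), np.int64(A), np.int64(pad),
        )
        if js < 0 or err_rep >= BIG or err_rep > self._err_budget:
            return None
        up_ok = eu1 >= 0
        dn_ok = ed1 >= 0
        if not up_ok and not dn_ok:
            # repeat-only read: real repeat coverage but no flank information.
            # The tighter error bound keeps reads that merely END inside the
            # repeat (whose truncation surfaces as edit errors) out of the
            # ambiguous bucket.
            if err_rep <= 0.5 * self.params.max_error_rate * self._rep_len:
                return ClassLabel.AMBIGUOUS.value, {"err_repeat": int(err_rep)}
            return ClassLabel.UNCLASSIFIED.value, {"err_repeat": int(err_rep)}
        if not (up_ok and dn_ok):
            return ClassLabel.UNCLASSIFIED.value, {"err_repeat": int(err_rep)}

        up_err = {1: int(eu1), 2: int(eu2)}
        dn_err = {1: int(ed1), 2: int(ed2)}
        core_len = self._rep_len + len(self._up[1]) + len(self._dn[1])
        anchor_len = max(1, len(self._up[1]) + len(self._dn[1]))
        identities: dict[ClassLabel, float] = {}
        anchor_identities: dict[ClassLabel, float] = {}
        for label, (u, d) in self._combos.items():
            total = int(err_rep) + up_err[u] + dn_err[d]
            identities[label] = 1.0 - total / core_len
            # the references differ only in their flanks, so the uniqueness
            # margin is measured over the anchors alone: it must not dilute
            # as the shared repeat grows longer
            anchor_identities[label] = 1.0 - (up_err[u] + dn_err[d]) / anchor_len
        qualifying = {
            lab: anchor_identities[lab]
            for lab, ident in identities.items()
            if 1.0 - ident <= self.params.max_error_rate
        }
        detail = {
            "err_repeat": int(err_rep),
            "identities": {k.value: v for k, v in identities.items()},
            "anchor_identities": {k.value: v for k, v in anchor_identities.items()},
        }
        if not qualifying:
            return ClassLabel.UNCLASSIFIED.value, detail
        ranked = sorted(qualifying.items(), key=lambda kv: -kv[1])
        if len(ranked) == 1:
            return ranked[0][0].value, detail
        if ranked[0][1] - ranked[1][1] >= self.params.min_identity_margin:
            return ranked[0][0].value, detail
        return ClassLabel.AMBIGUOUS.value, detail

    # -- public API --------------------------------------------------------

    def classify(self, read: str | Read) -> ClassLabel:
        seq = read.seq if isinstance(read, Read) else read
        if not seq:
            return ClassLabel.UNCLASSIFIED
        fwd = encode(seq)
        rev = np.where(fwd < 4, 3 - fwd, 4).astype(np.uint8)[::-1].copy()
        results = []
        for enc in (fwd, rev):
            res = self._classify_oriented(enc)
            if res is not None:
                results.append(res)
        if not results:
            return ClassLabel.UNCLASSIFIED
        # when both orientations locate the repeat, trust the cleaner one
        results.sort(key=lambda r: r[1]["err_repeat"])
        return ClassLabel(results[0][0])


def classify_read(
    read: str | Read,
    refs: Mapping[str, ConformationReference],
    params: ClassificationParams | None = None,
) -> ClassLabel:
    """Classify a single read; prefer :func:`count_support` for many reads."""
    return PairClassifier(refs, params).classify(read)


def count_support(
    reads: Iterable[str | Read],
    refs: Mapping[str, ConformationReference],
    params: ClassificationParams | None = None,
) -> ReadSupportCounts:
    """Tally :func:`classify_read` over all reads (deterministic)."""
    clf = PairClassifier(refs, params)
    counts = ReadSupportCounts(pair_id=clf.pair_id)
    slot = {
        ClassLabel.MAJOR1: "m1",
        ClassLabel.MAJOR2: "m2",
        ClassLabel.ALT1: "a1",
        ClassLabel.ALT2: "a2",
        ClassLabel.AMBIGUOUS: "ambiguous",
        ClassLabel.UNCLASSIFIED: "unclassified",
    }
    for read in reads:
        label = clf.classify(read)
        setattr(counts, slot[label], getattr(counts, slot[label]) + 1)
    return counts
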