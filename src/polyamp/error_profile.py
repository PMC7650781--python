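"""Per-substitution sequencing-error estimation from reads over a known
sequence.

Barcode regions are ideal for this: the true sequence of every base is known
by construction, so any disagreement between a read and its accession's
barcode (or other anchored known region) is a sequencing error. Rates are
estimated per ordered base pair, rate[x][y] = errors x read as y divided by
opportunities (positions whose truth is x); Illumina substitution error is
direction-biased (elevated G->A), which an unordered summary would blur, so
the ordered matrix is primary and an unordered view is offered alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core_model import DataError, logger

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to indices 0..3; anything else (incl. N) -> -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class SubstitutionMatrix:
    """Ordered substitution counts and rates over ACGT.

    ``counts[x, y]`` is the number of observed bases whose truth is x and
    read base is y (diagonal = matches); ``opportunities[x]`` is the number
    of assessed positions with truth x. A rate with zero opportunities is
    undefined and reported as missing (NaN).
    """

    counts: np.ndarray = field(default_factory=lambda: np.zeros((4, 4), dtype=np.int64))
    n_reads: int = 0
    n_skipped: int = 0

    @property
    def opportunities(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def rate(self, from_base: str, to_base: str) -> float:
        """Error rate for one ordered pair; NaN when undefined."""
        x, y = _BASE_INDEX[from_base], _BASE_INDEX[to_base]
        opp = self.opportunities[x]
        if opp == 0:
            return float("nan")
        return self.counts[x, y] / opp

    def rates(self) -> pd.DataFrame:
        """4x4 ordered-rate table (rows: truth, cols: read base); diagonal is
        the per-base accuracy; undefined rows are NaN."""
        opp = self.opportunities.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(opp[:, None] > 0, self.counts / opp[:, None], np.nan)
        return pd.DataFrame(r, index=list(BASES), columns=list(BASES))

    def unordered_rates(self) -> pd.DataFrame:
        """Strand/direction-agnostic summary: for each unordered pair {x, y},
        pooled errors (x->y plus y->x) over pooled opportunities."""
        rows = []
        for i in range(4):
            for j in range(i + 1, 4):
                opp = self.opportunities[i] + self.opportunities[j]
                err = self.counts[i, j] + self.counts[j, i]
                rows.append(
                    {
                        "pair": f"{BASES[i]}/{BASES[j]}",
                        "rate": err / opp if opp else float("nan"),
                        "opportunities": int(opp),
                    }
                )
        return pd.DataFrame(rows)


def substitution_rates(
    reads: Iterable[str], truth: str, truths: Optional[Iterable[str]] = None
) -> SubstitutionMatrix:
    """Tally per-substitution error rates from reads positionally aligned to
    a known sequence.

    Each read must have the same length as its truth (reads are anchored by
    exact position, e.g. a barcode prefix; no gapped alignment — barcodes are
    short and indel-free by construction). Length-mismatched reads are
    skipped with a log entry. Pass ``truths`` to give each read its own known
    sequence (e.g. per-accession barcodes); otherwise ``truth`` applies to
    all. Positions where either base is outside ACGT are not assessed.
    """
    matrix = SubstitutionMatrix()
    truth_list = list(truths) if truths is not None else None
    reads = list(reads)
    if truth_list is not None and len(truth_list) != len(reads):
        raise DataError("truths must match reads one-to-one")
    enc_cache: dict[str, np.ndarray] = {}
    for k, read in enumerate(reads):
        t = truth_list[k] if truth_list is not None else truth
        if len(read) != len(t):
            matrix.n_skipped += 1
            logger.warning(
                "substitution_rates: read %d length %d != truth length %d; skipped",
                k, len(read), len(t),
            )
            continue
        if t not in enc_cache:
            enc_cache[t] = _encode(t)
        te = enc_cache[t]
        re = _encode(read)
        ok = (te >= 0) & (re >= 0)
        np.add.at(matrix.counts, (te[ok], re[ok]), 1)
        matrix.n_reads += 1
    return matrix


def max_rate(matrix: SubstitutionMatrix) -> tuple[tuple[str, str], float, bool]:
    """The ordered pair with the highest error rate.

    Returns ((from, to), rate, tie_flag); ties are broken lexicographically
    on (from, to) and flagged. Raises DataError when every rate is undefined.
    """
    best: Optional[tuple[str, str]] = None
    best_rate = -1.0
    tie = False
    for x in BASES:
        for y in BASES:
            if x == y:
                continue
            r = matrix.rate(x, y)
            if np.isnan(r):
                continue
            if r > best_rate:
                best, best_rate, tie = (x, y), r, False
            elif r == best_rate:
                tie = True
    if best is None:
        raise DataError("no defined substitution rates")
    return best, best_rate, tie


def rates_table(matrix: SubstitutionMatrix) -> pd.DataFrame:
    """Long-form table of the 12 ordered substitution rates."""
    rows = []
    for x in BASES:
        for y in BASES:
            if x == y:
                continue
            rows.append(
                {
                    "from": x,
                    "to": y,
                    "rate": matrix.rate(x, y),
                    "errors": int(matrix.counts[_BASE_INDEX[x], _BASE_INDEX[y]]),
                    "opportunities": int(matrix.opportunities[_BASE_INDEX[x]]),
                }
            )
    return pd.DataFrame(rows)
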