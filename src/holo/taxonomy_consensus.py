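"""Subtype-level taxonomy from BLAST tabular hits.

Strain labels like ``C15au`` are reduced to their subtype (``C15``); a
query is assigned the modal subtype of its filtered best hits when that
subtype exceeds a consensus threshold, otherwise it stays unassigned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

# one clade letter followed by digits; anything after (strain letters etc.) dropped
_SUBTYPE_RE = re.compile(r"^([A-Z][0-9]+)")


def extract_subtype(strain_label: str) -> tuple[str, bool]:
    """Strip strain suffixes from a subtype label, e.g. C15au -> C15.

    Returns ``(subtype, matched)``; labels not matching the
    clade-letter-plus-digits pattern come back unmodified with
    ``matched=False``.
    """
    if not strain_label:
        raise ValueError("empty strain label")
    m = _SUBTYPE_RE.match(strain_label)
    if m is None:
        return strain_label, False
    return m.group(1), True


@dataclass(frozen=True)
class TaxonomyCall:
    """Consensus call for one query."""

    query_id: str
    subtype: str | None  # None = unassigned
    consensus: float
    n_retained: int

    @property
    def assigned(self) -> bool:
        return self.subtype is not None


def read_blast_outfmt6(path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular (``-outfmt 6``) file.

    Malformed rows are reported with their 1-based line numbers.
    """
    rows = []
    bad: list[int] = []
    with open(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                bad.append(lineno)
                continue
            try:
                rows.append(
                    {
                        "qseqid": parts[0],
                        "sseqid": parts[1],
                        "pident": float(parts[2]),
                        "length": int(parts[3]),
                        "mismatch": int(parts[4]),
                        "gapopen": int(parts[5]),
                        "qstart": int(parts[6]),
                        "qend": int(parts[7]),
                        "sstart": int(parts[8]),
                        "send": int(parts[9]),
                        "evalue": float(parts[10]),
                        "bitscore": float(parts[11]),
                    }
                )
            except ValueError:
                bad.append(lineno)
    if bad:
        raise ValueError(f"malformed BLAST rows at lines: {bad}")
    return pd.DataFrame(rows, columns=OUTFMT6_COLUMNS)


def assign_consensus(
    hits: pd.DataFrame,
    max_hits: int = 30,
    evalue_max: float = 1e-100,
    min_identity: float = 95.0,
    consensus_min: float = 0.90,
    strict_consensus: bool = True,
) -> TaxonomyCall:
    """Call the consensus subtype for one query's hit table.

    The best ``max_hits`` hits (bitscore desc, then e-value asc, then
    subject id — a total order, so input row order never matters) are
    filtered to e-value < ``evalue_max`` and identity > ``min_identity``;
    the modal subtype is assigned when its share among retained hits
    exceeds ``consensus_min`` (strictly, by default; set
    ``strict_consensus=False`` for >=). Zero retained hits give an
    unassigned call with consensus 0.
    """
    if evalue_max <= 0 or consensus_min <= 0:
        raise ValueError("thresholds must be positive")
    queries = hits["qseqid"].unique()
    if len(queries) != 1:
        raise ValueError(f"expected hits for a single query, got {len(queries)}")
    query = str(queries[0])

    ranked = hits.sort_values(
        ["bitscore", "evalue", "sseqid"], ascending=[False, True, True], kind="mergesort"
    ).head(max_hits)
    retained = ranked[(ranked["evalue"] < evalue_max) & (ranked["pident"] > min_identity)]
    n = len(retained)
    if n == 0:
        return TaxonomyCall(query, None, 0.0, 0)

    subtypes = retained["sseqid"].map(lambda s: extract_subtype(str(s))[0])
    shares = subtypes.value_counts(sort=True)
    top = str(shares.index[0])
    consensus = float(shares.iloc[0]) / n
    ok = consensus > consensus_min if strict_consensus else consensus >= consensus_min
    return TaxonomyCall(query, top if ok else None, consensus, n)


def assign_all(hits: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Consensus calls for every query in a combined hit table.

    Returns a table with columns query, subtype (NA when unassigned),
    consensus, n_retained.
    """
    calls = [
        assign_consensus(group, **kwargs)
        for _, group in hits.groupby("qseqid", sort=True)
    ]
    return pd.DataFrame(
        {
            "query": [c.query_id for c in calls],
            "subtype": [c.subtype if c.assigned else "NA" for c in calls],
            "consensus": [c.consensus for c in calls],
            "n_retained": [c.n_retained for c in calls],
        }
    )
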