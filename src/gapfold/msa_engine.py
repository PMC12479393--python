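"""a3m parsing and block-diagonal MSA merging over the merged pseudo-chain.

No sequence pairing is performed: every alignment row covers exactly one
chain's column block and is gap-padded over all the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from gapfold.template_engine import MergedTarget

logger = logging.getLogger(__name__)

GAP = "-"


class A3mFormatError(ValueError):
    """Raised when an a3m file is malformed."""


@dataclass
class ChainMSA:
    """Per-chain alignment: rows over query columns plus deletion counts.

    ``deletions[r][c]`` is the number of insertions (lowercase a3m
    characters) immediately preceding column ``c`` in row ``r``.
    """

    query: str
    rows: list[str]
    deletions: np.ndarray  # (n_rows, n_cols) int
    headers: list[str] = field(default_factory=list)
    source: str = "user_a3m"

    def __post_init__(self) -> None:
        self.deletions = np.asarray(self.deletions, dtype=np.int32)
        ncol = len(self.query)
        if not self.rows or self.rows[0] != self.query:
            raise ValueError("row 0 of a ChainMSA must equal the query")
        for i, row in enumerate(self.rows):
            if len(row) != ncol:
                raise ValueError(f"row {i} has {len(row)} columns, expected {ncol}")
        if self.deletions.shape != (len(self.rows), ncol):
            raise ValueError("deletions shape mismatch")
        if not self.headers:
            self.headers = [f"row{i}" for i in range(len(self.rows))]

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class MergedMSA:
    """Unpaired block-diagonal MSA over the merged query."""

    query: str
    rows: list[str]
    deletions: np.ndarray
    row_origin: list[object]  # "query" or source chain ordinal
    headers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.deletions = np.asarray(self.deletions, dtype=np.int32)
        if not self.rows or self.rows[0] != self.query:
            raise ValueError("row 0 of a MergedMSA must equal the merged query")
        for i, row in enumerate(self.rows):
            if len(row) != len(self.query):
                raise ValueError(f"merged row {i} has wrong column count")
        if len(self.row_origin) != len(self.rows):
            raise ValueError("row_origin length mismatch")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def write_a3m(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for header, row in zip(self.headers, self.rows):
                fh.write(f">{header}\n{row}\n")


def _strip_row(raw: str) -> tuple[str, list[int]]:
    """Remove lowercase insertions, counting them per following column."""
    columns: list[str] = []
    deletions: list[int] = []
    pending = 0
    for ch in raw:
        if ch.islower():
            pending += 1
        else:
            columns.append(ch)
            deletions.append(pending)
            pending = 0
    return "".join(columns), deletions


def parse_a3m(path: str | Path, max_rows: int | None = None) -> ChainMSA:
    """Parse an a3m file (lowercase = insertion, '-' = deletion).

    ``max_rows``, when set, keeps the first rows in file order (query
    always included).
    """
    path = Path(path)
    headers: list[str] = []
    raw_rows: list[str] = []
    current: list[str] = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if headers:
                raw_rows.append("".join(current))
            headers.append(line[1:].strip())
            current = []
        else:
            current.append(line)
    if headers:
        raw_rows.append("".join(current))
    if not raw_rows:
        raise A3mFormatError(f"{path}: no alignment rows")
    if max_rows is not None:
        headers = headers[:max_rows]
        raw_rows = raw_rows[:max_rows]
    query, query_del = _strip_row(raw_rows[0])
    if any(query_del):
        raise A3mFormatError(f"{path}: query row contains insertions")
    rows: list[str] = []
    deletions: list[list[int]] = []
    for i, raw in enumerate(raw_rows):
        stripped, dels = _strip_row(raw)
        if len(stripped) != len(query):
            raise A3mFormatError(
                f"{path}: row {i} has {len(stripped)} columns after insertion "
                f"stripping, expected {len(query)}"
            )
        rows.append(stripped)
        deletions.append(dels)
    return ChainMSA(
        query=query,
        rows=rows,
        deletions=np.asarray(deletions, dtype=np.int32),
        headers=headers,
        source="user_a3m",
    )


def single_sequence_msa(query: str, header: str = "query") -> ChainMSA:
    """MSA containing only the query itself (fallback when no a3m given)."""
    return ChainMSA(
        query=query,
        rows=[query],
        deletions=np.zeros((1, len(query)), dtype=np.int32),
        headers=[header],
    )


def merge_msas(chain_msas: list[ChainMSA], merged: MergedTarget) -> MergedMSA:
    """Merge per-chain MSAs block-diagonally over the merged query.

    Each non-query row of chain ``k`` is padded with gaps over every
    other chain's columns; the merged row count is
    ``1 + sum(rows - 1 per chain)`` and no row mixes chains.
    """
    if len(chain_msas) != merged.n_chains:
        raise ValueError(
            f"got {len(chain_msas)} chain MSAs for {merged.n_chains} chains"
        )
    n_cols = len(merged.sequence)
    offsets = merged.chain_offsets
    for k, msa in enumerate(chain_msas):
        expected = merged.sequence[merged.chain_slice(k)]
        if msa.query != expected:
            raise ValueError(
                f"chain {k} MSA query does not match the merged target chain"
            )
    rows = [merged.sequence]
    deletions = [np.zeros(n_cols, dtype=np.int32)]
    row_origin: list[object] = ["query"]
    headers = ["query"]
    for k, msa in enumerate(chain_msas):
        off = offsets[k]
        length = merged.chain_lengths[k]
        for r in range(1, msa.n_rows):
            padded = GAP * off + msa.rows[r] + GAP * (n_cols - off - length)
            dels = np.zeros(n_cols, dtype=np.int32)
            dels[off : off + length] = msa.deletions[r]
            rows.append(padded)
            deletions.append(dels)
            row_origin.append(k)
            headers.append(f"chain{k}/{msa.headers[r]}")
    return MergedMSA(
        query=merged.sequence,
        rows=rows,
        deletions=np.stack(deletions),
        row_origin=row_origin,
        headers=headers,
    )
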