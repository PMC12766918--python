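"""Term-to-member annotation tables and the sparse membership matrix.

An annotation table maps a term (e.g. a GO Biological Process) to the node
identifiers it annotates. ``build_matrix`` intersects the table with a
network and produces a binary node x term matrix in CSC form, row-aligned
to the network's canonical (lexicographic) node order. Term-size filtering
follows standard overrepresentation practice: terms outside
[min_size, max_size] (sizes counted AFTER intersection with the network)
are dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .network import Network

logger = logging.getLogger(__name__)

__all__ = ["AnnotationMatrix", "AnnotationError", "read_annotations", "build_matrix"]


class AnnotationError(ValueError):
    pass


@dataclass
class AnnotationMatrix:
    """Binary membership matrix aligned to a network.

    matrix
        ``scipy.sparse`` CSC matrix, shape (N, T), entries in {0, 1};
        row i is network node i in canonical order.
    term_ids
        Ordered term identifiers (column j is ``term_ids[j]``).
    term_names
        Optional human-readable descriptions.
    universe_mask
        Boolean row mask defining the statistical universe. All-true by
        default; restricted to annotated rows when the matrix was built
        with ``annotated_universe=True``.
    report
        Bookkeeping from construction: dropped terms, unmatched members.
    """

    matrix: sp.csc_matrix
    term_ids: tuple[str, ...]
    node_ids: tuple[str, ...]
    term_names: dict[str, str] | None = None
    universe_mask: np.ndarray | None = None
    report: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.universe_mask is None:
            self.universe_mask = np.ones(self.matrix.shape[0], dtype=bool)

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_terms(self) -> int:
        return self.matrix.shape[1]

    @property
    def coverage(self) -> int:
        """Number of network nodes carrying at least one annotation."""
        return int((self.matrix.sum(axis=1) > 0).sum())

    def term_sizes(self) -> np.ndarray:
        """Column sums within the universe (K_t per term)."""
        sub = self.matrix[self.universe_mask]
        return np.asarray(sub.sum(axis=0)).ravel().astype(np.int64)

    def term_index(self, term_id: str) -> int:
        try:
            return self.term_ids.index(term_id)
        except ValueError:
            raise KeyError(term_id) from None

    def members(self, term_id: str) -> list[str]:
        j = self.term_index(term_id)
        rows = self.matrix.getcol(j).tocoo().row
        return [self.node_ids[i] for i in rows]


# ----------------------------------------------------------------------


def read_annotations(path, fmt: str = "auto") -> dict[str, list[str]]:
    """Load a raw term->members mapping from JSON or long-format CSV/TSV.

    JSON must be an object ``{term: [node, ...]}``; CSV/TSV must have
    columns ``term`` and ``node``. Duplicate members are deduplicated per
    term (first occurrence kept).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise AnnotationError(f"{path}: empty annotation file")
    if fmt == "auto":
        fmt = {".json": "json", ".csv": "csv", ".tsv": "tsv"}.get(
            path.suffix.lower(), "json" if path.read_bytes()[:1] == b"{" else "tsv"
        )
    if fmt == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise AnnotationError(
                f"{path}: invalid JSON at line {e.lineno}: {e.msg}"
            ) from e
        if not isinstance(doc, dict):
            raise AnnotationError(f"{path}: expected a JSON object term->members")
        out = {}
        for term, members in doc.items():
            if not isinstance(members, (list, tuple)):
                raise AnnotationError(
                    f"{path}: term {term!r} maps to {type(members).__name__}, "
                    "expected a list"
                )
            out[str(term)] = list(dict.fromkeys(map(str, members)))
        return out
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, dtype=str)
        for col in ("term", "node"):
            if col not in df.columns:
                raise AnnotationError(f"{path}: missing required column {col!r}")
        bad = df.index[df["term"].isna() | df["node"].isna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise AnnotationError(f"{path}: malformed row at line {bad[0] + 2}")
        out = {}
        for term, node in zip(df["term"], df["node"]):
            out.setdefault(term, [])
            if node not in out[term]:
                out[term].append(node)
        return out
    raise ValueError(f"unknown annotation format {fmt!r}")


def build_matrix(
    mapping: Mapping[str, Sequence[str]],
    net: Network,
    min_size: int = 2,
    max_size: int | None = None,
    annotated_universe: bool = False,
    case_fold: bool = False,
    term_names: Mapping[str, str] | None = None,
) -> AnnotationMatrix:
    """Intersect a term->members mapping with a network and build the
    sparse membership matrix.

    Term sizes are counted on network-intersected members; terms with size
    outside ``[min_size, max_size]`` are dropped (``max_size=None`` means
    the universe size N). Members absent from the network are excluded and
    counted in the report. ``annotated_universe`` restricts the
    statistical universe to rows with at least one membership.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if max_size is not None and max_size < min_size:
        raise ValueError("max_size must be >= min_size")
    max_size = max_size if max_size is not None else net.n

    if case_fold:
        index = {v.casefold(): i for i, v in enumerate(net.nodes)}
        key = str.casefold
    else:
        index = {v: i for i, v in enumerate(net.nodes)}
        key = str

    rows: list[int] = []
    cols: list[int] = []
    kept_terms: list[str] = []
    dropped: dict[str, int] = {}
    unmatched = 0
    for term in mapping:
        members = dict.fromkeys(mapping[term])  # dedup, keep order
        idx = []
        for v in members:
            i = index.get(key(str(v)))
            if i is None:
                unmatched += 1
            else:
                idx.append(i)
        if min_size <= len(idx) <= max_size:
            j = len(kept_terms)
            kept_terms.append(str(term))
            rows.extend(idx)
            cols.extend([j] * len(idx))
        else:
            dropped[str(term)] = len(idx)

    if not kept_terms:
        raise AnnotationError(
            "no terms survived filtering; relax min_size/max_size "
            f"(dropped {len(dropped)} term(s))"
        )
    mat = sp.csc_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(net.n, len(kept_terms)),
    )
    mat.data[:] = 1  # guard against accidental duplicates summing to 2

    mask = None
    if annotated_universe:
        mask = np.asarray(mat.sum(axis=1)).ravel() > 0
    if unmatched:
        logger.info("%d annotation member(s) not present in the network", unmatched)
    names = (
        {t: str(term_names[t]) for t in kept_terms if t in term_names}
        if term_names
        else None
    )
    return AnnotationMatrix(
        matrix=mat,
        term_ids=tuple(kept_terms),
        node_ids=net.nodes,
        term_names=names,
        universe_mask=mask,
        report={"dropped_terms": dropped, "unmatched_members": unmatched},
    )
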