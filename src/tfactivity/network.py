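"""Signed TF-gene regulatory networks (wiring diagrams).

A network is the known map of which transcription factor regulates which
gene; it constrains activity inference. Edges may carry a regulation sign
(+1 activation, -1 repression) or be of unknown sign (0), mirroring
regulonDB-style interaction tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SIGN_TO_CHAR = {1: "+", -1: "-", 0: "?"}
_CHAR_TO_SIGN = {"+": 1, "-": -1, "?": 0}


@dataclass
class RegulatoryNetwork:
    """Binary TF-gene connectivity with optional interaction signs.

    Attributes
    ----------
    tf_ids : list of str
    gene_ids : list of str
    connectivity : ndarray of shape (n_genes, n_tfs)
        ``connectivity[g, f] == 1`` iff gene ``g`` is regulated by TF ``f``.
    signs : ndarray of shape (n_genes, n_tfs)
        +1 / -1 where the regulation sign is annotated, 0 where unknown.
        Zero wherever ``connectivity`` is zero.
    """

    tf_ids: list
    gene_ids: list
    connectivity: np.ndarray
    signs: np.ndarray = None

    def __post_init__(self):
        self.tf_ids = list(self.tf_ids)
        self.gene_ids = list(self.gene_ids)
        X = np.asarray(self.connectivity)
        if X.shape != (len(self.gene_ids), len(self.tf_ids)):
            raise ValueError(
                f"connectivity shape {X.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.tf_ids)} TFs"
            )
        if not np.isin(X, (0, 1)).all():
            raise ValueError("connectivity must be binary")
        self.connectivity = X.astype(np.int8)
        if self.signs is None:
            self.signs = np.zeros_like(self.connectivity)
        else:
            S = np.asarray(self.signs)
            if S.shape != X.shape:
                raise ValueError("signs shape must match connectivity")
            if not np.isin(S, (-1, 0, 1)).all():
                raise ValueError("signs must be in {-1, 0, +1}")
            if np.any((S != 0) & (X == 0)):
                raise ValueError("signs must be zero where connectivity is zero")
            self.signs = S.astype(np.int8)

    @property
    def n_tfs(self) -> int:
        return len(self.tf_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.connectivity.sum())

    def regulators_of(self, gene_id: str) -> list:
        g = self.gene_ids.index(gene_id)
        return [self.tf_ids[f] for f in np.flatnonzero(self.connectivity[g])]

    def subset_genes(self, gene_ids) -> "RegulatoryNetwork":
        """Restrict to the given genes, keeping all TF columns."""
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return RegulatoryNetwork(
            tf_ids=self.tf_ids,
            gene_ids=list(gene_ids),
            connectivity=self.connectivity[idx],
            signs=self.signs[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        """Edge list with columns TF, gene, sign (regulonDB flavour)."""
        gi, fi = np.nonzero(self.connectivity)
        return pd.DataFrame(
            {
                "TF": [self.tf_ids[f] for f in fi],
                "gene": [self.gene_ids[g] for g in gi],
                "sign": [_SIGN_TO_CHAR[int(self.signs[g, f])] for g, f in zip(gi, fi)],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, edges: pd.DataFrame) -> "RegulatoryNetwork":
        required = {"TF", "gene", "sign"}
        if not required.issubset(edges.columns):
            raise ValueError(f"edge table must have columns {sorted(required)}")
        tf_ids = sorted(edges["TF"].astype(str).unique())
        gene_ids = sorted(edges["gene"].astype(str).unique())
        f_of = {t: i for i, t in enumerate(tf_ids)}
        g_of = {g: i for i, g in enumerate(gene_ids)}
        X = np.zeros((len(gene_ids), len(tf_ids)), dtype=np.int8)
        S = np.zeros_like(X)
        for tf, gene, sign in edges[["TF", "gene", "sign"]].itertuples(index=False):
            sign = str(sign)
            if sign not in _CHAR_TO_SIGN:
                raise ValueError(f"unknown sign {sign!r}; expected one of + - ?")
            g, f = g_of[str(gene)], f_of[str(tf)]
            X[g, f] = 1
            S[g, f] = _CHAR_TO_SIGN[sign]
        return cls(tf_ids=tf_ids, gene_ids=gene_ids, connectivity=X, signs=S)

    @classmethod
    def from_tsv(cls, path) -> "RegulatoryNetwork":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))
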