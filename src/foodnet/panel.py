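"""Shared bipartite panel container used by every stage of the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class BipartitePanel:
    """One year of a bipartite country x product system.

    Attributes
    ----------
    year : int
        Calendar year the panel describes.
    countries, products : list of str
        Ordered, duplicate-free row / column labels.
    M : ndarray of int8, shape (n_countries, n_products)
        Binary production matrix; ``M[c, p] == 1`` iff country ``c``
        produces product ``p`` (strictly positive summed tonnage).
    W : ndarray of float, shape (n_countries, n_products)
        Per-capita weighted matrix in tons person^-1 year^-1.
        ``W[c, p] > 0`` exactly where ``M[c, p] == 1``.
    """

    year: int
    countries: list[str]
    products: list[str]
    M: np.ndarray
    W: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int8)
        self.W = np.asarray(self.W, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_c, n_p = len(self.countries), len(self.products)
        if self.M.shape != (n_c, n_p) or self.W.shape != (n_c, n_p):
            raise ValueError(
                f"matrix shape {self.M.shape}/{self.W.shape} does not match "
                f"{n_c} countries x {n_p} products"
            )
        if len(set(self.countries)) != n_c:
            raise ValueError("duplicate country labels")
        if len(set(self.products)) != n_p:
            raise ValueError("duplicate product labels")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("M must be binary")
        if (self.W < 0).any():
            raise ValueError("W must be non-negative")
        if not np.array_equal(self.W > 0, self.M == 1):
            raise ValueError("support of W must equal support of M")

    # -- convenience ------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape

    @property
    def n_links(self) -> int:
        """Number of (country, product) production links."""
        return int(self.M.sum())

    @property
    def fill(self) -> float:
        """Fraction of realized links (connectivity)."""
        return self.n_links / self.M.size if self.M.size else 0.0

    def zero_countries(self) -> list[str]:
        """Countries with an all-zero row (flagged, never dropped here)."""
        return [c for c, k in zip(self.countries, self.M.sum(axis=1)) if k == 0]

    def zero_products(self) -> list[str]:
        """Products with an all-zero column."""
        return [p for p, k in zip(self.products, self.M.sum(axis=0)) if k == 0]

    def country_index(self, label: str) -> int:
        try:
            return self.countries.index(label)
        except ValueError:
            raise KeyError(f"country {label!r} not in panel") from None

    @classmethod
    def from_weighted(
        cls, year: int, countries: list[str], products: list[str], W: np.ndarray, **meta
    ) -> "BipartitePanel":
        """Build a panel from a weighted matrix; support defines M."""
        W = np.asarray(W, dtype=float)
        return cls(year, list(countries), list(products), (W > 0).astype(np.int8), W, dict(meta))
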