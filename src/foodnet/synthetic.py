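"""Synthetic bipartite worlds with planted capabilities and difficulties.

The generator plants a per-country capability score and a per-product
difficulty score, both log-normal. A country produces every product whose
difficulty it can meet (capability >= difficulty), with a symmetric flip
probability ``noise``; at ``noise=0`` the support is perfectly nested.
Per-capita volumes are log-normal so downstream score distributions are
heavy-tailed. Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from foodnet.panel import BipartitePanel
from foodnet.tables import DEFAULT_MIN_POP


@dataclass
class PlantedWorld:
    """A synthetic panel together with its generating ground truth."""

    capabilities: pd.Series  # planted per-country score f*_c > 0
    difficulties: pd.Series  # planted per-product score q*_p > 0
    panel: BipartitePanel
    seed: int
    params: dict = field(default_factory=dict)

    def records(self) -> pd.DataFrame:
        """Long-format production records equivalent to the panel."""
        persons = np.asarray(self.params["persons"], dtype=float)
        rows = []
        for i, country in enumerate(self.panel.countries):
            for j, product in enumerate(self.panel.products):
                if self.panel.M[i, j]:
                    rows.append(
                        (country, product, self.panel.year,
                         self.panel.W[i, j] * persons[i])
                    )
        return pd.DataFrame(rows, columns=["country", "product", "year", "tonnes"])

    def population(self) -> pd.DataFrame:
        persons = np.asarray(self.params["persons"])
        return pd.DataFrame(
            {
                "country": self.panel.countries,
                "year": self.panel.year,
                "persons": persons.astype(int),
            }
        )

    def write_ground_truth(self, directory: str | Path) -> None:
        """Save planted scores as two-column TSVs."""
        directory = Path(directory)
        self.capabilities.rename("capability").to_csv(
            directory / "capabilities.tsv", sep="\t", index_label="country"
        )
        self.difficulties.rename("difficulty").to_csv(
            directory / "difficulties.tsv", sep="\t", index_label="product"
        )


def _labels(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def simulate_panel(
    n_countries: int = 177,
    n_products: int = 157,
    noise: float = 0.05,
    volume_sigma: float = 1.0,
    seed: int = 0,
    year: int = 2011,
    pop_range: tuple[int, int] = (600_000, 50_000_000),
) -> PlantedWorld:
    """Generate a planted-capability bipartite world.

    ``M[c, p]`` is 1 with probability ``1 - noise`` when the country's
    capability meets the product's difficulty and with probability
    ``noise`` otherwise, so ``noise=0`` yields a perfectly nested
    support. Where ``M=1``, tonnage is ``persons * LogNormal(0,
    volume_sigma^2)`` so the per-capita weight is log-normal.

    Raises
    ------
    ValueError for degenerate parameters (sizes < 2, noise outside
    [0, 0.5], non-positive volume_sigma, population range at or below
    the default filter threshold).
    """
    if n_countries < 2 or n_products < 2:
        raise ValueError("need at least 2 countries and 2 products")
    if not 0.0 <= noise <= 0.5:
        raise ValueError(f"noise must be in [0, 0.5], got {noise}")
    if volume_sigma <= 0:
        raise ValueError("volume_sigma must be positive")
    if pop_range[0] <= DEFAULT_MIN_POP or pop_range[1] < pop_range[0]:
        raise ValueError("population range must lie above the 500,000 filter")

    rng = np.random.default_rng(seed)
    capabilities = rng.lognormal(0.0, 1.0, n_countries)
    difficulties = rng.lognormal(0.0, 1.0, n_products)

    can_produce = capabilities[:, None] >= difficulties[None, :]
    flips = rng.random((n_countries, n_products)) < noise
    M = (can_produce ^ flips).astype(np.int8)

    per_capita = np.exp(rng.normal(0.0, volume_sigma, (n_countries, n_products)))
    W = np.where(M == 1, per_capita, 0.0)
    persons = rng.integers(pop_range[0], pop_range[1], size=n_countries, endpoint=True)

    countries = _labels("C", n_countries)
    products = _labels("P", n_products)
    panel = BipartitePanel(year, countries, products, M, W)
    return PlantedWorld(
        capabilities=pd.Series(capabilities, index=countries, name="capability"),
        difficulties=pd.Series(difficulties, index=products, name="difficulty"),
        panel=panel,
        seed=seed,
        params={
            "n_countries": n_countries,
            "n_products": n_products,
            "noise": noise,
            "volume_sigma": volume_sigma,
            "pop_range": pop_range,
            "persons": persons,
            "year": year,
        },
    )


def simulate_random_panel(
    n_countries: int,
    n_products: int,
    n_links: int,
    seed: int | np.random.Generator = 0,
    year: int = 0,
) -> BipartitePanel:
    """Random bipartite panel with exactly ``n_links`` links placed
    uniformly at random without replacement (the null-ensemble generator:
    same dimensions and same number of links as the observed matrix).
    """
    n_cells = n_countries * n_products
    if not 0 <= n_links <= n_cells:
        raise ValueError(f"n_links must be in [0, {n_cells}], got {n_links}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_links, replace=False)
    M = np.zeros(n_cells, dtype=np.int8)
    M[flat] = 1
    M = M.reshape(n_countries, n_products)
    return BipartitePanel(
        year, _labels("C", n_countries), _labels("P", n_products), M, M.astype(float)
    )
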