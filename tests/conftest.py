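"""Shared fixtures and small random-study builders."""

from __future__ import annotations

import numpy as np
import pytest

from themesort import QuoteCorpus, RaterSort, SortStudy
from themesort.network import from_weights


def random_sort(rng: np.random.Generator, quote_ids, rater_id: str, max_groups: int = 6) -> RaterSort:
    """A uniformly random partition of the given quotes into <= max_groups."""
    n_groups = int(rng.integers(1, max_groups + 1))
    return RaterSort(
        rater_id=rater_id,
        assignment={q: f"g{int(rng.integers(n_groups))}" for q in quote_ids},
    )


def random_study(rng: np.random.Generator, n_quotes: int, n_raters: int, max_groups: int = 6) -> SortStudy:
    quote_ids = list(range(1, n_quotes + 1))
    return SortStudy(
        corpus=QuoteCorpus.from_ids(quote_ids),
        sorts=[random_sort(rng, quote_ids, f"r{r}", max_groups) for r in range(n_raters)],
    )


@pytest.fixture
def two_triangles():
    """Two disjoint unit-weight triangles: the classic modularity fixture."""
    return from_weights(
        {(1, 2): 1, (2, 3): 1, (1, 3): 1, (4, 5): 1, (5, 6): 1, (4, 6): 1}
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
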