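"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache
from itertools import product

import pytest

from msytree import AFRICAN_CLADES, refine
from msytree.refpanel import reference_panel


@pytest.fixture(scope="session")
def panel():
    return reference_panel()


@pytest.fixture(scope="session")
def refined_result(panel):
    return refine(
        panel.backbone,
        panel.matrix,
        panel.catalog,
        panel.outgroup,
        region_filter=AFRICAN_CLADES,
    )


# ---------------------------------------------------------------------------
# oracle: exhaustive enumeration of rooted multifurcating trees
#
# A rooted tree on a labeled leaf set is equivalent to its clade family
# (a laminar family containing the universe and all singletons), so trees
# are enumerated as clade families via set partitions of the root.


def _set_partitions(items: tuple) -> list[list[tuple]]:
    if not items:
        return [[]]
    first, rest = items[0], items[1:]
    out = []
    for part in _set_partitions(rest):
        for i in range(len(part)):
            out.append(part[:i] + [(first,) + part[i]] + part[i + 1 :])
        out.append([(first,)] + part)
    return out


@lru_cache(maxsize=None)
def enumerate_clade_families(leaves: tuple) -> list[frozenset]:
    """All rooted multifurcating tree shapes on ``leaves`` as clade sets."""
    if len(leaves) == 1:
        return [frozenset([frozenset(leaves)])]
    universe = frozenset(leaves)
    out = []
    for part in _set_partitions(leaves):
        if len(part) < 2:
            continue
        block_options = [enumerate_clade_families(tuple(sorted(b))) for b in part]
        for combo in product(*block_options):
            fam = frozenset().union(*combo) | {universe}
            out.append(frozenset(fam))
    return out
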