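from collections import deque

import pytest
from hypothesis import settings

from cytobarcode import load_fixture, parse_banding

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

STANDARD_LABELS = "abcdefghijklmnopqr"
NEW_SPECIES_IIL = "aedhionjkbcfglmqpr"

DERIVATION_LINES = [
    "IIL-complex a: a[ed/hi/on/jk/bc]fg/lm/qp/r",
    "IIL-complex b: a[cb]kj/no/ih/defg/lm/qp/r",
    "IIL-complex c: abc[kj/no/ih/defg]lm/qp/r",
    "IIL-complex d: abc[gfed]hi/on/jklm/qp/r",
    "IIL-2: abcdefghi/on/jklm[qp]r",
    "IIL-3: abcdefghi/on[jklm]pqr",
    "IIL-1: abcdefghi[onmlkj]pqr",
    "Standard: abcdefghijklmnopqr",
]


@pytest.fixture(scope="session")
def standard_seq():
    return parse_banding(STANDARD_LABELS, STANDARD_LABELS)


@pytest.fixture(scope="session")
def new_species_seq(standard_seq):
    return parse_banding(NEW_SPECIES_IIL, standard_seq.labels)


@pytest.fixture(scope="session")
def registry_profiles():
    return load_fixture("table1_registry")


@pytest.fixture(scope="session")
def alias_table():
    return load_fixture("aliases")


def bfs_reversal_distances(n):
    """Distance from the identity to every permutation of length n, by BFS.

    Independent oracle for the reversal-distance search: plain breadth-first
    enumeration of permutation states under all interval reversals.
    """
    ident = tuple(range(n))
    dist = {ident: 0}
    queue = deque([ident])
    moves = [(i, j) for i in range(n - 1) for j in range(i + 1, n)]
    while queue:
        p = queue.popleft()
        d = dist[p]
        for i, j in moves:
            child = p[:i] + p[i : j + 1][::-1] + p[j + 1 :]
            if child not in dist:
                dist[child] = d + 1
                queue.append(child)
    return dist


@pytest.fixture(scope="session")
def bfs_tables():
    return {n: bfs_reversal_distances(n) for n in range(2, 9)}
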