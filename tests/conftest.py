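import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def levenshtein(a: str, b: str) -> int:
    """Plain DP edit distance — independent oracle for alignment code."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_rotation_distance(a: str, b: str) -> tuple[int, int]:
    """Exhaustive (rotation, distance) minimization — test oracle.

    Rotation is a right rotation (last r characters move to the front).
    """
    best = (0, levenshtein(a, b))
    for r in range(1, len(a)):
        d = levenshtein(a[-r:] + a[:-r], b)
        if d < best[1]:
            best = (r, d)
    return best


@pytest.fixture
def rotation_oracle():
    return brute_rotation_distance


def brute_force_msn(dm) -> set:
    """Union of all minimum spanning trees by exhaustive enumeration
    (independent oracle for the union-find MSN construction)."""
    import networkx as nx

    g = nx.Graph()
    names = list(dm.index)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            g.add_edge(a, b, weight=float(dm.loc[a, b]))
    best, edges = None, set()
    for tree in nx.SpanningTreeIterator(g):  # yields trees by weight
        w = sum(d["weight"] for _u, _v, d in tree.edges(data=True))
        if best is None or w < best - 1e-9:
            best, edges = w, set()
        if abs(w - best) <= 1e-9:
            edges |= {frozenset((u, v)) for u, v in tree.edges()}
        if w > best + 1e-9:
            break
    return edges
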