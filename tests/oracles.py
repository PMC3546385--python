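"""Independent oracles: Wright path-counting kinship and random pedigrees.

The oracle enumerates, for each common ancestor A of two individuals, every
pair of ascending paths meeting only at A, and sums
(1/2)^(n1 + n2 + 1) * (1 + f_A).  It shares no code with the package's
tabular kinship engine.
"""

from __future__ import annotations

import numpy as np

from matekin.pedigree import FEMALE, MALE, Pedigree


def _ascending_paths(parents: dict, start: str) -> list[tuple]:
    """All maternal/paternal chains from ``start`` upward (inclusive)."""
    out = []

    def rec(path):
        out.append(tuple(path))
        for p in parents[path[-1]]:
            if p is not None:
                rec(path + [p])

    rec([start])
    return out


def kinship_oracle(parents: dict, i: str, j: str, _memo=None) -> float:
    """Path-counting kinship; ``parents``: id -> (mother, father)."""
    if _memo is None:
        _memo = {}
    if i == j:
        return 0.5 * (1.0 + inbreeding_oracle(parents, i, _memo))
    total = 0.0
    for P in _ascending_paths(parents, i):
        for Q in _ascending_paths(parents, j):
            if P[-1] != Q[-1]:
                continue
            if set(P[:-1]) & set(Q[:-1]):
                continue  # paths may meet only at the common ancestor
            ancestor = P[-1]
            n1, n2 = len(P) - 1, len(Q) - 1
            f_a = inbreeding_oracle(parents, ancestor, _memo)
            total += 0.5 ** (n1 + n2 + 1) * (1.0 + f_a)
    return total


def inbreeding_oracle(parents: dict, i: str, _memo=None) -> float:
    if _memo is None:
        _memo = {}
    if i in _memo:
        return _memo[i]
    m, f = parents[i]
    val = 0.0 if (m is None or f is None) else kinship_oracle(parents, f, m, _memo)
    _memo[i] = val
    return val


def random_pedigree(rng: np.random.Generator, n: int = 20, n_generations: int = 4,
                    p_known_parent: float = 0.8) -> Pedigree:
    """Random multi-generation pedigree with valid sex/birth-order links."""
    records = []
    by_gen: list[list[tuple[str, str]]] = []
    k = 0
    for g in range(n_generations):
        size = max(2, int(round(n / n_generations)))
        if g == n_generations - 1:
            size = max(2, n - k)
        layer = []
        for _ in range(size):
            iid = f"I{k:03d}"
            sex = FEMALE if rng.random() < 0.5 else MALE
            mother = father = None
            if g > 0:
                earlier = [x for gen in by_gen for x in gen]
                mothers = [i for i, s in earlier if s == FEMALE]
                fathers = [i for i, s in earlier if s == MALE]
                if mothers and rng.random() < p_known_parent:
                    mother = mothers[rng.integers(len(mothers))]
                if fathers and rng.random() < p_known_parent:
                    father = fathers[rng.integers(len(fathers))]
            records.append(
                {
                    "id": iid,
                    "sex": sex,
                    "birth_year": 1970 + 5 * g,
                    "death_year": None,
                    "mother_id": mother,
                    "father_id": father,
                    "matriline_id": None,
                }
            )
            layer.append((iid, sex))
            k += 1
        by_gen.append(layer)
    return Pedigree.from_records(records)


def parents_dict(ped: Pedigree) -> dict:
    df = ped.to_frame()
    return {
        r.id: (r.mother_id, r.father_id) for r in df.itertuples(index=False)
    }
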