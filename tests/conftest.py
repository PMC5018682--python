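"""Shared fixtures: synthetic records with ground truth, scoring scheme."""

import pytest

from opsin_charter import (OpsinParams, ScoringScheme, load_reference_identity_matrix,
                           make_opsin)


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def complete_opsin():
    """A synthetic opsin with every hallmark planted, plus its truth."""
    return make_opsin(7)


@pytest.fixture(scope="session")
def reference_identity():
    """The packaged published identity matrix over the nine opsins."""
    return load_reference_identity_matrix()


def brute_force_align_score(a: str, b: str, scoring: ScoringScheme) -> float:
    """Exhaustive-enumeration oracle for the optimal global alignment score.

    Explores every monotone alignment path; a gap run of length L costs
    gap_open + L * gap_extend, terminal gaps included. Feasible for
    lengths <= 8.
    """
    go, ge = scoring.gap_open, scoring.gap_extend
    best = [float("-inf")]

    def rec(i: int, j: int, acc: float, prev: str) -> None:
        if i == len(a) and j == len(b):
            if acc > best[0]:
                best[0] = acc
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, acc + scoring.score(a[i], b[j]), "M")
        if i < len(a):
            rec(i + 1, j, acc - (ge if prev == "X" else go + ge), "X")
        if j < len(b):
            rec(i, j + 1, acc - (ge if prev == "Y" else go + ge), "Y")

    rec(0, 0, 0.0, "")
    return best[0]


def brute_force_iupac_scan(text: str, pattern: str) -> list:
    """Sliding-window oracle: start positions matching the IUPAC pattern."""
    from opsin_charter.core_io import IUPAC_SETS

    sets = [IUPAC_SETS[p] for p in pattern]
    return [s for s in range(len(text) - len(pattern) + 1)
            if all(text[s + k] in sets[k] for k in range(len(pattern)))]
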