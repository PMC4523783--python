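"""RNA secondary-structure folding backends.

A folding backend is any callable ``seq -> (dot_bracket, energy)``.  The
default backend wraps the ViennaRNA thermodynamic engine.  A bundled
Nussinov-style maximum-pairing backend with a stacking-weighted energy
surrogate is provided for environments without ViennaRNA; it is explicitly
non-thermodynamic and its "energies" must not be read as kcal/mol minimum
free energies.

Downstream hairpin-criteria logic consumes only ``(structure, energy)`` and
is therefore backend-independent; tests may inject stub backends returning
fixed structures.
"""

from __future__ import annotations

from typing import Callable, List, Tuple

from ._seq import as_dna, as_rna, can_pair, is_watson_crick, is_wobble

FoldBackend = Callable[[str], Tuple[str, float]]

_MIN_LOOP = 3

# stacking-weighted pair scores for the surrogate energy (arbitrary units,
# scaled to resemble kcal/mol magnitudes for strong hairpins)
_PAIR_SCORE = {"GC": 3.0, "CG": 3.0, "AT": 2.0, "TA": 2.0, "GT": 1.0, "TG": 1.0}


def vienna_fold(seq: str) -> Tuple[str, float]:
    """Minimum-free-energy fold via ViennaRNA; returns (dot-bracket, kcal/mol)."""
    import RNA

    structure, mfe = RNA.fold(as_rna(seq))
    return structure, float(mfe)


def nussinov_fold(seq: str) -> Tuple[str, float]:
    """Maximum-pairing fold (Nussinov DP) with a stacking-weighted surrogate energy.

    Not thermodynamic: suitable for structure-shaped logic only, never for
    MFE-threshold claims.
    """
    s = as_dna(seq)
    n = len(s)
    if n == 0:
        return "", 0.0
    # dp[i][j] = best score of subsequence i..j (inclusive)
    dp = [[0.0] * n for _ in range(n)]
    for span in range(_MIN_LOOP + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - _MIN_LOOP):
                pair = s[k] + s[j]
                if pair in _PAIR_SCORE:
                    left = dp[i][k - 1] if k > i else 0.0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                    # reward contiguous stacking slightly
                    cand = left + inner + _PAIR_SCORE[pair]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if dp[i][j] == (dp[i][j - 1] if j - 1 >= i else 0.0):
                j -= 1
                continue
            for k in range(i, j - _MIN_LOOP):
                pair = s[k] + s[j]
                if pair in _PAIR_SCORE:
                    left = dp[i][k - 1] if k > i else 0.0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                    if abs(dp[i][j] - (left + inner + _PAIR_SCORE[pair])) < 1e-9:
                        structure[k] = "("
                        structure[j] = ")"
                        if k > i:
                            traceback(i, k - 1)
                        traceback(k + 1, j - 1)
                        return
            j -= 1  # defensive; should not be reached

    traceback(0, n - 1)
    return "".join(structure), -dp[0][n - 1]


def get_backend(name: str = "auto") -> FoldBackend:
    """Resolve a folding backend by name: 'vienna', 'nussinov' or 'auto'."""
    if name == "vienna":
        return vienna_fold
    if name == "nussinov":
        return nussinov_fold
    if name == "auto":
        try:
            import RNA  # noqa: F401

            return vienna_fold
        except ImportError:
            return nussinov_fold
    raise ValueError(f"unknown folding backend: {name!r}")


def pair_table(structure: str) -> List[int]:
    """0-based partner index per position (-1 = unpaired) from dot-bracket.

    Raises ValueError on unbalanced brackets.
    """
    pt = [-1] * len(structure)
    stack: List[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"unexpected structure character {c!r} at {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pt


__all__ = [
    "FoldBackend",
    "vienna_fold",
    "nussinov_fold",
    "get_backend",
    "pair_table",
    "can_pair",
    "is_watson_crick",
    "is_wobble",
]
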