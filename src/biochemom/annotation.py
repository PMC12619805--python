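"""Spectral-library matching for candidate features.

A deliberately minimal annotation step: library candidates are screened by
precursor m/z tolerance, then scored by cosine similarity on square-root
scaled fragment intensities with greedy one-to-one peak matching.  A
mirror-plot export writes the query (positive) and library (negated)
intensity lists for manual comparison, the standard visual check before
trusting any putative identification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import Spectrum

__all__ = ["MatchResult", "cosine_similarity", "cosine_match", "export_mirror"]


@dataclass
class MatchResult:
    query_id: str
    library_id: str
    cosine: float
    matched_peaks: list[tuple[float, float]]  # (query m/z, library m/z) pairs
    precursor_delta: float                    # Da


def _matched_pairs(
    query: Spectrum, library: Spectrum, fragment_tol: float
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one peak pairing within ``fragment_tol``.

    Candidate pairs are ranked by the product of unit-normalized sqrt
    intensities (best pair first); each peak is used at most once.
    """
    qi = np.sqrt(query.intensity_array)
    li = np.sqrt(library.intensity_array)
    qn = np.linalg.norm(qi)
    ln = np.linalg.norm(li)
    if qn == 0 or ln == 0:
        return []
    qi, li = qi / qn, li / ln
    pairs = []
    for a, qmz in enumerate(query.mz_array):
        close = np.flatnonzero(np.abs(library.mz_array - qmz) <= fragment_tol)
        for b in close:
            pairs.append((qi[a] * li[b], a, int(b)))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_q: set[int] = set()
    used_l: set[int] = set()
    out = []
    for score, a, b in pairs:
        if a in used_q or b in used_l:
            continue
        used_q.add(a)
        used_l.add(b)
        out.append((a, b, score))
    return out


def cosine_similarity(query: Spectrum, library: Spectrum, fragment_tol: float = 0.02) -> float:
    """Cosine of sqrt-intensity vectors over greedily matched peaks (0..1)."""
    return float(sum(s for _, _, s in _matched_pairs(query, library, fragment_tol)))


def cosine_match(
    query: Spectrum,
    library: list[Spectrum],
    precursor_tol: float = 0.01,
    fragment_tol: float = 0.02,
) -> list[MatchResult]:
    """Rank library spectra against a query.

    Library entries outside ``precursor_tol`` of the query precursor are
    skipped.  Results are sorted by descending cosine (ties by library id).
    """
    if precursor_tol <= 0 or fragment_tol <= 0:
        raise ValueError("tolerances must be > 0")
    results = []
    for lib in library:
        delta = lib.precursor_mz - query.precursor_mz
        if abs(delta) > precursor_tol:
            continue
        pairs = _matched_pairs(query, lib, fragment_tol)
        results.append(
            MatchResult(
                query_id=query.identifier,
                library_id=lib.identifier,
                cosine=float(sum(s for *_, s in pairs)),
                matched_peaks=[
                    (float(query.mz_array[a]), float(lib.mz_array[b]))
                    for a, b, _ in pairs
                ],
                precursor_delta=float(delta),
            )
        )
    results.sort(key=lambda r: (-r.cosine, r.library_id))
    return results


def export_mirror(query: Spectrum, match: Spectrum, path) -> None:
    """Write mirror-plot data: query up (positive), library down (negated).

    Intensities are normalized so each block's base peak is 100.
    """
    rows = []
    for spec, sign, label in ((query, 1.0, "query"), (match, -1.0, "library")):
        base = spec.intensity_array.max()
        if base <= 0:
            raise ValueError(f"{label} spectrum has no positive intensity")
        for mz, inten in spec.peaks:
            rows.append(
                {"spectrum": label, "identifier": spec.identifier,
                 "mz": mz, "intensity": sign * 100.0 * inten / base}
            )
    pd.DataFrame(rows, columns=["spectrum", "identifier", "mz", "intensity"]).to_csv(
        path, index=False
    )
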