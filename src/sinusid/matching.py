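"""Brute-force Hamming matching and the mean-distance similarity score.

The similarity score between an antemortem (AM) and a postmortem (PM)
image is the arithmetic mean of the Hamming distances of brute-force
matched descriptor pairs: each AM (query) descriptor is paired with its
nearest PM (target) descriptor, every query is matched (no ratio test, no
cross-check), and ties at equal distance go to the lowest target index.
Lower scores mean more similar images; identical images score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import BinaryDescriptor, DescriptorSet, FeatureError, InsufficientFeaturesError


@dataclass(frozen=True)
class MatchSet:
    """One (query_index, target_index, hamming_distance) triple per query
    descriptor."""

    pairs: tuple[tuple[int, int, int], ...]
    query_method: str

    def distances(self) -> np.ndarray:
        return np.array([d for (_, _, d) in self.pairs], dtype=float)


@dataclass(frozen=True)
class SimilarityScore:
    """Mean matched Hamming distance between two images (in bits)."""

    value: float
    n_matches: int
    method: str
    direction: str = "AM->PM"


def hamming(d1: BinaryDescriptor, d2: BinaryDescriptor) -> int:
    """Number of differing bits between two descriptors of the same
    method and length."""
    if d1.method != d2.method or d1.nbits != d2.nbits:
        raise FeatureError(
            f"cannot compare descriptors: {d1.method}/{d1.nbits} vs {d2.method}/{d2.nbits}"
        )
    return int(np.bitwise_count(np.bitwise_xor(d1.bits, d2.bits)).sum())


def hamming_matrix(query: DescriptorSet, target: DescriptorSet) -> np.ndarray:
    """(n_query, n_target) matrix of pairwise Hamming distances."""
    if query.method != target.method or query.nbits != target.nbits:
        raise FeatureError("descriptor sets differ in method or bit length")
    q = query.bits
    t = target.bits
    return np.bitwise_count(q[:, None, :] ^ t[None, :, :]).sum(axis=2, dtype=np.int32)


def brute_force_match(query: DescriptorSet, target: DescriptorSet) -> MatchSet:
    """Exhaustive nearest-neighbour matching: every query descriptor is
    paired with the target descriptor at minimal Hamming distance (ties
    resolved to the lowest target index)."""
    if len(query) == 0 or len(target) == 0:
        raise InsufficientFeaturesError("brute-force matching needs non-empty descriptor sets")
    dist = hamming_matrix(query, target)
    idx = np.argmin(dist, axis=1)  # first occurrence = lowest target index
    pairs = tuple(
        (int(i), int(j), int(dist[i, j])) for i, j in enumerate(idx)
    )
    return MatchSet(pairs=pairs, query_method=query.method)


def score_from_descriptors(query: DescriptorSet, target: DescriptorSet,
                           symmetric: bool = False) -> SimilarityScore:
    """Similarity score from pre-extracted descriptor sets (AM as query)."""
    ms = brute_force_match(query, target)
    value = float(ms.distances().mean())
    n = len(ms.pairs)
    if symmetric:
        ms2 = brute_force_match(target, query)
        value = 0.5 * (value + float(ms2.distances().mean()))
        n += len(ms2.pairs)
        return SimilarityScore(value=value, n_matches=n, method=query.method,
                               direction="symmetric")
    return SimilarityScore(value=value, n_matches=n, method=query.method)


def similarity_score(image_am, image_pm, method: str = "akaze", params=None,
                     symmetric: bool = False) -> SimilarityScore:
    """Extract features from both images with the chosen method and return
    the mean matched Hamming distance (AM -> PM).

    Raises :class:`InsufficientFeaturesError` when either image yields no
    keypoints; the cohort layer records such pairs as missing, never 0.
    """
    extract = _extractor(method)
    _, d_am = extract(image_am, params)
    _, d_pm = extract(image_pm, params)
    return score_from_descriptors(d_am, d_pm, symmetric=symmetric)


def _extractor(method: str):
    if method == "akaze":
        from .akaze import akaze_extract
        return akaze_extract
    if method == "orb":
        from .orb import orb_extract
        return orb_extract
    raise ValueError(f"unknown method {method!r}; expected 'akaze' or 'orb'")
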