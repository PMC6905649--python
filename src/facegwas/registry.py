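"""Landmark and phenotype name registries.

Thirteen standard facial landmarks (bilateral exocanthion/endocanthion,
nasion, pronasale, subnasale, bilateral alare, labiale superius/inferius,
bilateral cheilion) and the 78 = C(13,2) inter-landmark Euclidean distances
derived from them.  Distance names are canonicalized as ``"<LM1>-<LM2>"``
with landmark order fixed by the registry so that each pair has exactly one
name.
"""

from __future__ import annotations

import itertools

#: Canonical order of the 13 facial landmarks.
LANDMARK_NAMES: tuple[str, ...] = (
    "ExR", "ExL", "EnR", "EnL", "Nsn", "Prn", "Sbn",
    "AlR", "AlL", "Ls", "Li", "ChR", "ChL",
)

_INDEX = {name: i for i, name in enumerate(LANDMARK_NAMES)}

N_LANDMARKS = len(LANDMARK_NAMES)


def distance_name(a: str, b: str) -> str:
    """Canonical name of the distance between landmarks *a* and *b*."""
    if a not in _INDEX or b not in _INDEX:
        unknown = [x for x in (a, b) if x not in _INDEX]
        raise KeyError(f"unknown landmark name(s): {unknown}")
    if a == b:
        raise ValueError(f"distance requires two distinct landmarks, got {a!r} twice")
    i, j = sorted((_INDEX[a], _INDEX[b]))
    return f"{LANDMARK_NAMES[i]}-{LANDMARK_NAMES[j]}"


def distance_endpoints(name: str) -> tuple[str, str]:
    """Inverse of :func:`distance_name`."""
    a, _, b = name.partition("-")
    if not b or a not in _INDEX or b not in _INDEX:
        raise KeyError(f"not a canonical distance name: {name!r}")
    return a, b


#: The 78 canonical distance phenotype names, in registry pair order.
DISTANCE_NAMES: tuple[str, ...] = tuple(
    f"{a}-{b}" for a, b in itertools.combinations(LANDMARK_NAMES, 2)
)

#: Index pairs (i, j), i < j, matching :data:`DISTANCE_NAMES`.
DISTANCE_PAIRS: tuple[tuple[int, int], ...] = tuple(
    itertools.combinations(range(N_LANDMARKS), 2)
)
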