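"""Class structures (length bins, ages, sex-length bins) and growth matrices.

The three stocks use different demographic structures:

* hake — length bins: 1 cm on [1, 40) cm, 2 cm on [40, 100) cm, 10 cm on
  [100, 130) cm and a terminal 130+ plus-group (73 classes);
* sole — 7 age classes, first at age 2, terminal plus-group (ages 0-1 are
  not modelled);
* Norway lobster — one mixed recruitment class plus 2-mm carapace-length
  bins per sex: 33 male classes ([10, 74) mm plus a 74+ plus-group) and 23
  female classes ([10, 54) mm plus a 54+ plus-group).

Growth over one event (a monthly increment for hake, a moult for Norway
lobster) is encoded as a column-stochastic transition matrix built under a
uniform-within-bin assumption: mass in a source bin [a, b) shifted by the
class increment d spreads uniformly over [a+d, b+d) and is apportioned to
destination bins by interval overlap.  This construction is what removes the
artefact that appears when individuals grow from a narrow bin into a wider
one (naive whole-bin jumps inflate mean growth); by construction the mean
length after one application equals the mean length before plus the class
increment for every non-terminal class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassStructure",
    "build_class_structures",
    "build_transition_matrix",
    "apply_growth",
    "hake_structure",
    "sole_structure",
    "nephrops_structure",
]

SEX_NONE = ""
SEX_MALE = "M"
SEX_FEMALE = "F"
SEX_RECRUIT = "R"  # Norway lobster mixed recruitment class


@dataclass(frozen=True)
class ClassStructure:
    """Ordered demographic classes for one stock.

    ``lower``/``upper`` hold bin edges (cm for hake, carapace mm for Norway
    lobster, years for sole ages).  ``plus_group`` flags the terminal class of
    each sex track.  ``sex`` is one of "", "M", "F", "R" per class; non-sexed
    stocks use "" throughout.
    """

    kind: str  # "length-bin" | "age" | "sex-length-bin"
    labels: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray
    plus_group: np.ndarray  # bool per class
    sex: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        n = len(self.labels)
        if not (len(self.lower) == len(self.upper) == len(self.plus_group) == n):
            raise ValueError("class structure arrays must all have the same length")
        if not self.sex:
            object.__setattr__(self, "sex", (SEX_NONE,) * n)
        for track in self.sex_tracks():
            lo, hi = self.lower[track], self.upper[track]
            if np.any(np.diff(lo) <= 0):
                raise ValueError("bin edges must be strictly increasing within a sex")
            if np.any(lo[1:] != hi[:-1]):
                raise ValueError("bins must be contiguous within a sex")
            if self.plus_group[track].sum() != 1 or not self.plus_group[track][-1]:
                raise ValueError("exactly one terminal plus-group per sex track")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def sex_tracks(self) -> list[np.ndarray]:
        """Index arrays of the contiguous growth tracks (one per sex)."""
        tracks = []
        for s in dict.fromkeys(self.sex):  # preserve order
            if s == SEX_RECRUIT:
                continue
            tracks.append(np.flatnonzero(np.asarray(self.sex) == s))
        return tracks

    @property
    def midpoints(self) -> np.ndarray:
        """Mean length/age per class (lower edge for plus-groups)."""
        mid = 0.5 * (self.lower + self.upper)
        return np.where(self.plus_group, self.lower, mid)


def _binned(edges: list[float], sex: str = SEX_NONE, unit: str = "") -> tuple:
    lower = np.asarray(edges[:-1], dtype=float)
    upper = np.asarray(edges[1:], dtype=float)
    labels = [f"{sex}{'_' if sex else ''}[{lo:g},{hi:g})" for lo, hi in zip(lower, upper)]
    return lower, upper, labels


def hake_structure() -> ClassStructure:
    """Hake length structure: 1 cm bins on [1,40), 2 cm on [40,100), 10 cm on
    [100,130), terminal 130+ plus-group."""
    edges = list(range(1, 40)) + list(range(40, 100, 2)) + [100, 110, 120, 130]
    lower, upper, labels = _binned([float(e) for e in edges])
    lower = np.append(lower, 130.0)
    upper = np.append(upper, 140.0)  # nominal width; plus-group is absorbing
    labels.append("[130+]")
    plus = np.zeros(len(labels), dtype=bool)
    plus[-1] = True
    return ClassStructure("length-bin", tuple(labels), lower, upper, plus)


def sole_structure() -> ClassStructure:
    """Sole age structure: 7 classes from age 2 with a terminal plus-group."""
    ages = np.arange(2.0, 9.0)
    labels = tuple(f"age{int(a)}" for a in ages[:-1]) + ("age8+",)
    plus = np.zeros(7, dtype=bool)
    plus[-1] = True
    return ClassStructure("age", labels, ages, ages + 1.0, plus)


def nephrops_structure() -> ClassStructure:
    """Norway lobster sex-length structure.

    One mixed recruitment class at 0 mm, then 2-mm carapace-length bins:
    males [10,74) plus a 74+ plus-group (33 classes), females [10,54) plus a
    54+ plus-group (23 classes).
    """
    lowers = [0.0]
    uppers = [2.0]
    labels = ["recruit"]
    sexes = [SEX_RECRUIT]
    plus = [False]
    for sex, top in ((SEX_MALE, 74), (SEX_FEMALE, 54)):
        edges = [float(e) for e in range(10, top + 2, 2)]
        lo, up, labs = _binned(edges, sex=sex)
        lowers.extend(lo)
        uppers.extend(up)
        labels.extend(labs)
        sexes.extend([sex] * len(lo))
        plus.extend([False] * len(lo))
        lowers.append(float(top))
        uppers.append(float(top) + 2.0)
        labels.append(f"{sex}_[{top}+]")
        sexes.append(sex)
        plus.append(True)
    return ClassStructure(
        "sex-length-bin",
        tuple(labels),
        np.asarray(lowers),
        np.asarray(uppers),
        np.asarray(plus, dtype=bool),
        tuple(sexes),
    )


def build_class_structures() -> dict[str, ClassStructure]:
    """The three stock structures keyed by stock name."""
    return {
        "hake": hake_structure(),
        "sole": sole_structure(),
        "nephrops": nephrops_structure(),
    }


def build_transition_matrix(increments: np.ndarray, structure: ClassStructure) -> np.ndarray:
    """Growth transition matrix T (destination x source), column-stochastic.

    ``increments`` gives the per-class growth over one event in the
    structure's length unit; plus-group increments are forced to 0 (absorbing).
    Mass from bin [a, b) with increment d is spread uniformly over
    [a+d, b+d) and split across destination bins by overlap, mass beyond the
    last real bin accruing to the sex track's plus-group.  The uniform spread
    is what guarantees the mean-length drift equals the increment exactly,
    even when growing from a narrow bin into a wider one.
    """
    g = np.asarray(increments, dtype=float)
    if g.shape != (structure.n_classes,):
        raise ValueError(
            f"increments shape {g.shape} does not match {structure.n_classes} classes"
        )
    if np.any(g < 0):
        raise ValueError("growth increments must be non-negative (no shrinking)")
    n = structure.n_classes
    T = np.zeros((n, n))
    in_track = np.zeros(n, dtype=bool)
    for track in structure.sex_tracks():
        in_track[track] = True
        plus_idx = track[-1]
        for j in track:
            if structure.plus_group[j]:
                T[j, j] = 1.0  # absorbing
                continue
            a, b = structure.lower[j], structure.upper[j]
            d = g[j]
            lo, hi = a + d, b + d
            width = b - a
            remaining = 1.0
            for k in track:
                if structure.plus_group[k]:
                    continue
                c, e = structure.lower[k], structure.upper[k]
                overlap = max(0.0, min(hi, e) - max(lo, c)) / width
                if overlap > 0:
                    T[k, j] += overlap
                    remaining -= overlap
            if remaining > 1e-12:  # overflow past the last real bin
                T[plus_idx, j] += remaining
    # classes outside any track (the mixed recruitment class) stay put here;
    # their sex split at moult is population-level behaviour, not growth.
    for j in range(n):
        if not in_track[j]:
            T[j, j] = 1.0
    colsums = T.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-9):
        raise AssertionError("transition matrix is not column-stochastic")
    T[:, :] = T / colsums  # absorb rounding, keep exact stochasticity
    return T


def apply_growth(abundance: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Apply a growth transition to abundance-at-class.

    ``abundance`` may be 1-D (classes,) or 2-D (zones, classes); per-zone
    totals are conserved exactly because T is column-stochastic.
    """
    T = np.asarray(T)
    if abundance.shape[-1] != T.shape[1]:
        raise ValueError("abundance / transition-matrix dimension mismatch")
    if abundance.ndim == 1:
        return T @ abundance
    return abundance @ T.T
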