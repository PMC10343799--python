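"""Handedness indices from scalar triple products.

Two complementary indices are provided:

* the *Calpha index*: support vectors connect consecutive Calpha atoms in
  chain order; the sum of triple products of consecutive vector triples is
  parity-odd, so its sign detects the screw sense (positive = right-handed
  = D, negative = left-handed = L),
* the *dipole index*: the same construction applied to the per-unit dipole
  moment vectors (computed about each unit's mass-weighted center) ordered
  along the helix, for any number of units.

A normalized variant divides every triple product by
``C_i = (1/3) * (|v_i|^k + |v_{i+1}|^k + |v_{i+2}|^k)`` with configurable
exponent ``k`` (default 5); the dipole index is normalized by the cube of
the mean dipole magnitude.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .structures import Assembly, attach_charges

SIGN_RIGHT = "D"
SIGN_LEFT = "L"
SIGN_ACHIRAL = "achiral"
SIGN_MIXED = "mixed"

DEFAULT_K = 5
DEFAULT_MIXED_THRESHOLD = 0.25


class ChiralityError(ValueError):
    pass


class InsufficientStructureError(ChiralityError):
    pass


class DegenerateGeometryError(ChiralityError):
    pass


class MissingChargeError(ChiralityError):
    pass


class NormalizationUndefinedError(ChiralityError):
    """Mean dipole magnitude is zero; carries the partial report."""

    def __init__(self, message: str, report: "ChiralityReport"):
        super().__init__(message)
        self.report = report


@dataclasses.dataclass
class CalphaChiralityParams:
    k: int = DEFAULT_K
    window: int | None = None

    def validate(self) -> None:
        if self.k < 0:
            raise ChiralityError("k must be >= 0")


@dataclasses.dataclass
class ChiralityProfile:
    """Signed per-window index values from a sliding window over Calphas."""

    window: int
    values: np.ndarray
    mixed_threshold: float = DEFAULT_MIXED_THRESHOLD

    @property
    def fraction_positive(self) -> float:
        n = len(self.values)
        return float((self.values > 0).sum() / n) if n else 0.0

    @property
    def fraction_negative(self) -> float:
        n = len(self.values)
        return float((self.values < 0).sum() / n) if n else 0.0

    @property
    def label(self) -> str:
        fp, fn = self.fraction_positive, self.fraction_negative
        if fp >= self.mixed_threshold and fn >= self.mixed_threshold:
            return SIGN_MIXED
        if fp == fn:
            return SIGN_ACHIRAL
        return SIGN_RIGHT if fp > fn else SIGN_LEFT


@dataclasses.dataclass
class ChiralityReport:
    """Results of one or both chirality computations.

    Unset fields stay None: the Calpha path fills ``x_total``/``chi_norm``,
    the dipole path fills ``c_total``/``c_norm``/``d_av``.
    """

    x_total: float | None = None     # A^3
    chi_norm: float | None = None    # dimensionless (for k = 3; see docs)
    c_total: float | None = None     # (e*A)^3
    c_norm: float | None = None      # dimensionless
    d_av: float | None = None        # e*A
    sign_label: str = SIGN_ACHIRAL
    profile: ChiralityProfile | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.profile is not None:
            d["profile"] = {
                "window": self.profile.window,
                "values": list(map(float, self.profile.values)),
                "fraction_positive": self.profile.fraction_positive,
                "fraction_negative": self.profile.fraction_negative,
                "label": self.profile.label,
            }
        return d


def _sign_label(value: float) -> str:
    if value > 0:
        return SIGN_RIGHT
    if value < 0:
        return SIGN_LEFT
    return SIGN_ACHIRAL


def triple_product(v1, v2, v3) -> float:
    """Scalar triple product from the explicit component expression.

    Equals ``det[v1 | v2 | v3]``; kept in component form deliberately so an
    independent determinant can serve as a cross-check.
    """
    x1, y1, z1 = v1
    x2, y2, z2 = v2
    x3, y3, z3 = v3
    return float(
        (y1 * z2 - y2 * z1) * x3
        + (z1 * x2 - z2 * x1) * y3
        + (x1 * y2 - x2 * y1) * z3
    )


def _consecutive_triple_products(vectors: np.ndarray) -> np.ndarray:
    """Triple products of (V_i, V_{i+1}, V_{i+2}) for all i, vectorized."""
    a, b, c = vectors[:-2], vectors[1:-1], vectors[2:]
    return (
        (a[:, 1] * b[:, 2] - b[:, 1] * a[:, 2]) * c[:, 0]
        + (a[:, 2] * b[:, 0] - b[:, 2] * a[:, 0]) * c[:, 1]
        + (a[:, 0] * b[:, 1] - b[:, 0] * a[:, 1]) * c[:, 2]
    )


def calpha_vectors(assembly: Assembly) -> np.ndarray:
    """Support vectors between consecutive Calpha atoms, chain order."""
    idx = assembly.calpha_indices()
    if len(idx) < 4:
        raise InsufficientStructureError(
            f"need >= 4 Calpha atoms, found {len(idx)}"
        )
    return np.diff(assembly.coords[idx], axis=0)


def chirality_from_points(points: np.ndarray, k: int = DEFAULT_K) -> ChiralityReport:
    """Calpha-style index computed directly from an ordered point set."""
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        raise InsufficientStructureError("need >= 4 points")
    vectors = np.diff(points, axis=0)
    return chirality_from_vectors(vectors, k=k)


def chirality_from_vectors(vectors: np.ndarray, k: int = DEFAULT_K) -> ChiralityReport:
    vectors = np.asarray(vectors, dtype=float)
    norms = np.linalg.norm(vectors, axis=1)
    zero = np.flatnonzero(norms == 0)
    if len(zero):
        raise DegenerateGeometryError(
            f"zero-length support vector between Calpha pair "
            f"{zero[0] + 1}-{zero[0] + 2}"
        )
    triples = _consecutive_triple_products(vectors)
    x_total = float(triples.sum())
    c_i = (norms[:-2] ** k + norms[1:-1] ** k + norms[2:] ** k) / 3.0
    chi_norm = float((triples / c_i).sum())
    return ChiralityReport(
        x_total=x_total, chi_norm=chi_norm, sign_label=_sign_label(x_total)
    )


def calpha_chirality(assembly: Assembly,
                     params: CalphaChiralityParams | None = None) -> ChiralityReport:
    """Calpha triple-product index of an assembly; optional window profile."""
    params = params or CalphaChiralityParams()
    params.validate()
    vectors = calpha_vectors(assembly)
    report = chirality_from_vectors(vectors, k=params.k)
    if params.window is not None:
        report.profile = chirality_profile(assembly, params.window)
    return report


def chirality_profile(assembly: Assembly, window: int,
                      mixed_threshold: float = DEFAULT_MIXED_THRESHOLD) -> ChiralityProfile:
    """Sliding-window signed index over the Calpha trace.

    ``window`` counts Calpha atoms per window (>= 4).  The profile label is
    'mixed' when both signs each occupy at least ``mixed_threshold`` of the
    windows.
    """
    if window < 4:
        raise ChiralityError("window must cover >= 4 Calpha atoms")
    idx = assembly.calpha_indices()
    if len(idx) < window:
        raise InsufficientStructureError(
            f"assembly has {len(idx)} Calpha atoms, window is {window}"
        )
    points = assembly.coords[idx]
    values = np.array([
        chirality_from_points(points[s:s + window]).x_total
        for s in range(len(points) - window + 1)
    ])
    return ChiralityProfile(window=window, values=values,
                            mixed_threshold=mixed_threshold)


# ---------------------------------------------------------------------------
# Dipole-based index
# ---------------------------------------------------------------------------

def _resolve_charges(assembly: Assembly, charge_source) -> np.ndarray:
    """Charges per atom from records, a table, or the bundled defaults."""
    if charge_source == "records" or charge_source is None:
        q = assembly.charges
        if np.isnan(q).any():
            if charge_source == "records":
                missing = [assembly.names[i]
                           for i in np.flatnonzero(np.isnan(q))][:10]
                raise MissingChargeError(
                    f"atoms without charge: {', '.join(missing)}"
                )
            q = attach_charges(assembly.copy()).charges
        return q
    if charge_source == "default":
        return attach_charges(assembly.copy()).charges
    if isinstance(charge_source, dict):
        return attach_charges(assembly.copy(), charge_source).charges
    raise ChiralityError(f"unknown charge source {charge_source!r}")


def unit_dipole(assembly: Assembly, unit_id: int,
                charge_source=None) -> np.ndarray:
    """Dipole moment (e*A) of one unit about its mass-weighted center."""
    q = _resolve_charges(assembly, charge_source)
    idx = assembly.unit_indices(unit_id)
    if len(idx) == 0:
        raise ChiralityError(f"no unit {unit_id}")
    com = assembly.com(idx)
    return ((assembly.coords[idx] - com) * q[idx, None]).sum(axis=0)


def unit_dipoles(assembly: Assembly, charge_source=None) -> np.ndarray:
    q = _resolve_charges(assembly, charge_source)
    out = np.zeros((assembly.n_units, 3))
    for u in range(1, assembly.n_units + 1):
        idx = assembly.unit_indices(u)
        com = assembly.com(idx)
        out[u - 1] = ((assembly.coords[idx] - com) * q[idx, None]).sum(axis=0)
    return out


def dipole_chirality_from_vectors(dipoles: np.ndarray) -> ChiralityReport:
    """Triple-product index over an ordered set of dipole vectors (any n >= 3)."""
    dipoles = np.asarray(dipoles, dtype=float)
    if len(dipoles) < 3:
        raise InsufficientStructureError("need >= 3 dipole vectors")
    c_total = float(_consecutive_triple_products(dipoles).sum())
    d_av = float(np.linalg.norm(dipoles, axis=1).mean())
    report = ChiralityReport(
        c_total=c_total, d_av=d_av, sign_label=_sign_label(c_total)
    )
    if d_av == 0:
        raise NormalizationUndefinedError(
            "mean dipole magnitude is zero; c_norm undefined", report
        )
    report.c_norm = c_total / d_av ** 3
    return report


def dipole_chirality(assembly: Assembly, charge_source=None) -> ChiralityReport:
    """Dipole-moment triple-product index over units in helix order."""
    if assembly.n_units < 3:
        raise InsufficientStructureError("need >= 3 units")
    return dipole_chirality_from_vectors(unit_dipoles(assembly, charge_source))
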