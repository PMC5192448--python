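"""Natural-abundance correction of isotopologue distributions.

The measured isotopologue abundances of a 13C-enriched fatty acid (the mass
distribution vector, MDV) mix the tracer signal with natural heavy isotopes
of C, H and O.  A lower-triangular correction matrix is built whose column j
is the theoretical isotope pattern of the species with exactly j carbons
fixed as 13C and natural abundance everywhere else; solving ``C x = m``
recovers the tracer-only distribution (the corrected MDV), from which the
fractional 13C labelling is computed as the position-weighted mean.

The matrix follows the elemental-convolution construction of the standard
metabolic-flux correction literature: the pattern of a formula is the
convolution of each element's abundance vector with itself, atom by atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

from .fatty_acids import MolecularFormula
from .isotopes import IsotopeTable

__all__ = [
    "MDV",
    "CorrectionMatrix",
    "LabelingResult",
    "element_distribution",
    "natural_spectrum",
    "build_correction_matrix",
    "correct_mdv",
    "fractional_labeling",
    "percent_incorporation",
]


@dataclass
class MDV:
    """Mass distribution vector: abundances of M+0 .. M+n.

    ``values`` may be raw peak areas or fractions; ``normalized`` records
    whether the entries sum to one.  Length is always tracer-atom count + 1.
    """

    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("MDV must be a non-empty 1-D vector")
        if np.any(self.values < 0):
            raise ValueError("MDV entries must be non-negative")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("normalized MDV must sum to 1")

    @property
    def n_carbons(self) -> int:
        return self.values.size - 1

    def normalize(self) -> "MDV":
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero MDV")
        return MDV(self.values / total, normalized=True)


@dataclass
class CorrectionMatrix:
    """(n+1)x(n+1) lower-triangular map from tracer to measured distribution."""

    matrix: np.ndarray
    formula: MolecularFormula

    @property
    def n(self) -> int:
        return self.matrix.shape[0] - 1

    def forward(self, tracer: np.ndarray) -> np.ndarray:
        """Predicted measured MDV for a tracer distribution (exact model)."""
        return self.matrix @ np.asarray(tracer, dtype=float)


@dataclass
class LabelingResult:
    corrected_mdv: MDV
    fraction_labeled: float
    n_carbons: int
    residual_norm: float = 0.0
    n_clipped: int = 0
    clipped_mass: float = 0.0


def element_distribution(
    element: str, atom_count: int, table: IsotopeTable
) -> np.ndarray:
    """Isotope pattern of ``atom_count`` atoms of one element.

    The atom_count-fold self-convolution of the element's abundance vector;
    for carbon this is Binomial(atom_count, 0.0107) over 13C counts.  Zero
    atoms give the neutral element [1.0].
    """
    if atom_count < 0:
        raise ValueError(f"atom_count must be >= 0, got {atom_count}")
    base = table[element]
    out = np.array([1.0])
    for _ in range(atom_count):
        out = np.convolve(out, base)
    return out


def natural_spectrum(
    formula: MolecularFormula, table: IsotopeTable, length: int | None = None
) -> np.ndarray:
    """Isotope pattern of a whole formula: convolution over all elements.

    Truncated or zero-padded to ``length`` when given (mass beyond the
    window is dropped, not folded back).
    """
    spectrum = np.array([1.0])
    for elem, count in formula.element_counts:
        spectrum = np.convolve(spectrum, element_distribution(elem, count, table))
    if length is not None:
        if length < 1:
            raise ValueError("length must be >= 1")
        if spectrum.size >= length:
            spectrum = spectrum[:length]
        else:
            spectrum = np.pad(spectrum, (0, length - spectrum.size))
    return spectrum


def build_correction_matrix(
    formula: MolecularFormula,
    table: IsotopeTable | None = None,
    carbon_natural: bool = True,
) -> CorrectionMatrix:
    """Correction matrix for a carbon-bearing formula.

    Column j is the isotope pattern of the formula with j carbons fixed as
    13C (shifting the pattern down j rows) and natural abundance on the
    remaining atoms.  With ``carbon_natural=False`` the non-fixed carbons
    are treated as pure 12C, the convention of tracer-purity-style
    corrections; the default includes their natural 13C.
    """
    table = table or IsotopeTable.natural()
    n_c = formula["C"]
    if n_c < 1:
        raise ValueError("formula must contain at least one carbon")
    size = n_c + 1
    rest = MolecularFormula.from_dict(
        {e: c for e, c in formula.element_counts if e != "C"}, formula.charge
    )
    rest_spectrum = natural_spectrum(rest, table)
    matrix = np.zeros((size, size))
    for j in range(size):
        n_free = n_c - j if carbon_natural else 0
        col = np.convolve(element_distribution("C", n_free, table), rest_spectrum)
        upto = min(col.size, size - j)
        matrix[j : j + upto, j] = col[:upto]
    return CorrectionMatrix(matrix=matrix, formula=formula)


def correct_mdv(
    raw: MDV | np.ndarray,
    cm: CorrectionMatrix,
    method: str = "triangular",
    divisor: str = "n_carbons",
) -> LabelingResult:
    """Remove natural-abundance contributions from a measured MDV.

    Solves ``cm.matrix @ x = raw`` by forward substitution (equivalent to
    multiplying by the matrix inverse).  Negative entries — noise artefacts
    — are clipped to zero and the vector renormalised; the clip count and
    mass, and the residual of the clipped solution, are kept as diagnostics
    so dynamic-range problems stay visible.  ``method="nnls"`` solves a
    non-negative least-squares problem instead, for noisy data.
    """
    values = raw.values if isinstance(raw, MDV) else np.asarray(raw, dtype=float)
    if values.ndim != 1 or values.size != cm.matrix.shape[0]:
        raise ValueError(
            f"MDV length {values.size} does not match correction matrix "
            f"dimension {cm.matrix.shape[0]}"
        )
    if np.any(values < 0):
        raise ValueError("raw MDV entries must be non-negative")
    if method == "triangular":
        x = solve_triangular(cm.matrix, values, lower=True)
    elif method == "nnls":
        x, _ = nnls(cm.matrix, values)
    else:
        raise ValueError(f"unknown correction method {method!r}")
    negatives = x < 0
    clipped = x.copy()
    clipped[negatives] = 0.0
    total = clipped.sum()
    if total <= 0:
        raise ValueError("corrected MDV is all zero; input carries no signal")
    corrected = MDV(clipped / total, normalized=True)
    residual = float(np.linalg.norm(cm.matrix @ clipped - values))
    return LabelingResult(
        corrected_mdv=corrected,
        fraction_labeled=fractional_labeling(corrected, divisor=divisor),
        n_carbons=corrected.n_carbons,
        residual_norm=residual,
        n_clipped=int(negatives.sum()),
        clipped_mass=float(-x[negatives].sum()),
    )


def fractional_labeling(
    corrected: MDV | np.ndarray, divisor: str = "n_carbons"
) -> float:
    """Position-weighted fractional labelling of a corrected MDV.

    Each isotopologue is weighted by its label count (M+2 by 2, M+3 by 3,
    ...) and the weighted sum divided by nC times the unweighted sum, where
    nC is the carbon count (vector length minus one).  This is the mean
    fraction of carbon positions carrying 13C: 0 for an unlabelled pool,
    1 for a fully labelled one.  ``divisor="n_isotopologues"`` divides by
    nC + 1 instead, in which case full labelling reads nC/(nC+1).
    """
    values = corrected.values if isinstance(corrected, MDV) else np.asarray(
        corrected, dtype=float
    )
    total = values.sum()
    if total <= 0:
        raise ValueError("fractional labelling of an all-zero vector is undefined")
    n_c = values.size - 1
    if divisor == "n_carbons":
        denom = n_c
    elif divisor == "n_isotopologues":
        denom = n_c + 1
    else:
        raise ValueError(f"unknown divisor convention {divisor!r}")
    if denom == 0:
        raise ValueError("vector of length 1 has no labelable positions")
    weighted = float(np.dot(np.arange(values.size), values))
    return weighted / (denom * total)


def percent_incorporation(
    result: LabelingResult | float, pool_size: float
) -> float:
    """Labelled amount = fraction labelled x pool size (units of pool_size)."""
    if pool_size < 0:
        raise ValueError(f"pool size must be non-negative, got {pool_size}")
    fraction = (
        result.fraction_labeled if isinstance(result, LabelingResult) else float(result)
    )
    return fraction * pool_size
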