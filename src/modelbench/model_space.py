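"""The 88-model space of time-reversible nucleotide substitution models.

The registry is the Cartesian product of 11 exchangeability symmetry
classes (JC/F81 through SYM/GTR), two stationary-frequency modes (equal
vs. estimated), and four among-site rate-heterogeneity variants
(none, +I, +G, +I+G): 11 x 2 x 4 = 88 named models.  These are the
models offered by the common selection programs for DNA data.

A symmetry class partitions the six unordered nucleotide pairs
{AC, AG, AT, CG, CT, GT} into shared-rate groups, written as a six-digit
code in that pair order ("010010" groups the two transitions AG and CT).
The number of free exchangeability parameters is the number of distinct
groups minus one (one rate is the reference).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, UnknownModelError

#: Unordered nucleotide pairs, in the conventional code order.
PAIRS = ("AC", "AG", "AT", "CG", "CT", "GT")

#: Index pairs into the A,C,G,T state order for each entry of PAIRS.
_PAIR_INDEX = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

# (symmetry code, equal-frequency name, estimated-frequency name)
_FAMILIES = (
    ("000000", "JC", "F81"),
    ("010010", "K80", "HKY"),
    ("010020", "TrNef", "TrN"),
    ("012210", "TPM1", "TPM1uf"),
    ("010212", "TPM2", "TPM2uf"),
    ("012012", "TPM3", "TPM3uf"),
    ("012230", "TIM1ef", "TIM1"),
    ("010232", "TIM2ef", "TIM2"),
    ("012032", "TIM3ef", "TIM3"),
    ("012314", "TVMef", "TVM"),
    ("012345", "SYM", "GTR"),
)

_HET_SUFFIXES = ("", "+I", "+G", "+I+G")


@dataclass(frozen=True)
class SubstitutionModel:
    """One named member of the 88-model registry.

    Attributes
    ----------
    name : str
        Registry name, e.g. ``"HKY+I+G"``.
    symmetry_class : str
        Six-digit rate-class code over the pairs AC,AG,AT,CG,CT,GT.
    freq_mode : str
        ``"equal"`` (all 0.25) or ``"estimated"`` (3 free frequencies).
    plus_i : bool
        Invariant-sites proportion is a free parameter.
    plus_g : bool
        Gamma-distributed site rates (shape alpha) are modelled.
    """

    name: str
    symmetry_class: str
    freq_mode: str
    plus_i: bool
    plus_g: bool

    @property
    def n_rate_classes(self) -> int:
        return len(set(self.symmetry_class))

    @property
    def k_rates(self) -> int:
        return self.n_rate_classes - 1

    @property
    def k_freq(self) -> int:
        return 3 if self.freq_mode == "estimated" else 0

    @property
    def k_het(self) -> int:
        return int(self.plus_i) + int(self.plus_g)

    @property
    def k_model(self) -> int:
        """Free model parameters (exchangeabilities + frequencies + heterogeneity)."""
        return self.k_rates + self.k_freq + self.k_het

    @property
    def base_name(self) -> str:
        return self.name.replace("+I", "").replace("+G", "")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass(frozen=True)
class RateMatrix:
    """A normalized reversible instantaneous rate matrix with its stationary
    frequencies.  Rows/columns are ordered A, C, G, T; the matrix is scaled
    so that the expected substitution rate at stationarity is 1, making
    branch lengths expected substitutions per site."""

    Q: np.ndarray
    pi: np.ndarray

    def validate(self, atol: float = 1e-10) -> None:
        Q, pi = self.Q, self.pi
        if Q.shape != (4, 4) or pi.shape != (4,):
            raise InvalidInputError("rate matrix must be 4x4 with 4 frequencies")
        off = Q[~np.eye(4, dtype=bool)]
        if np.any(off < -atol):
            raise InvalidInputError("off-diagonal rates must be non-negative")
        if np.max(np.abs(Q.sum(axis=1))) > atol:
            raise InvalidInputError("rows of Q must sum to zero")
        flux = pi[:, None] * Q
        if np.max(np.abs(flux - flux.T)) > atol:
            raise InvalidInputError("Q violates detailed balance")
        if abs(-(pi * np.diag(Q)).sum() - 1.0) > atol:
            raise InvalidInputError("Q is not normalized to mean rate 1")


def _build_registry() -> tuple[SubstitutionModel, ...]:
    models = []
    for (code, eq_name, est_name), suffix in itertools.product(
        _FAMILIES, _HET_SUFFIXES
    ):
        for freq_mode, base in (("equal", eq_name), ("estimated", est_name)):
            models.append(
                SubstitutionModel(
                    name=base + suffix,
                    symmetry_class=code,
                    freq_mode=freq_mode,
                    plus_i="+I" in suffix,
                    plus_g="+G" in suffix,
                )
            )
    # Complexity order: free-parameter count, ties broken alphabetically.
    models.sort(key=lambda m: (m.k_model, m.name))
    return tuple(models)


_REGISTRY: tuple[SubstitutionModel, ...] = _build_registry()
_BY_NAME: dict[str, SubstitutionModel] = {m.name: m for m in _REGISTRY}
_RANK: dict[str, int] = {m.name: i + 1 for i, m in enumerate(_REGISTRY)}


def list_models() -> tuple[SubstitutionModel, ...]:
    """Return the full 88-model registry in complexity order.

    The order is stable and documented: ascending free-parameter count
    ``k_model``, ties broken by alphabetical name.
    """
    return _REGISTRY


def get_model(name: str) -> SubstitutionModel:
    """Look up a registry model by name.

    Raises
    ------
    UnknownModelError
        If ``name`` is not one of the 88 registry names.
    """
    try:
        return _BY_NAME[name]
    except KeyError:
        raise UnknownModelError(f"unknown substitution model: {name!r}") from None


def complexity_rank(model: SubstitutionModel | str) -> int:
    """Position (1..88) of ``model`` in the complexity-ordered registry."""
    name = model if isinstance(model, str) else model.name
    try:
        return _RANK[name]
    except KeyError:
        raise UnknownModelError(f"unknown substitution model: {name!r}") from None


def param_count(
    model: SubstitutionModel | str,
    n_taxa: int,
    include_branch_lengths: bool = True,
) -> int:
    """Number of free parameters charged to ``model`` by the criteria.

    With ``include_branch_lengths`` the 2t-3 branch lengths of an unrooted
    binary tree on ``n_taxa`` tips are added.  The branch-length term is
    constant across models on a fixed topology, so it never changes
    within-alignment rankings; including it matches the convention of the
    common selection programs.
    """
    if isinstance(model, str):
        model = get_model(model)
    if n_taxa < 3:
        raise InvalidInputError(f"n_taxa must be >= 3, got {n_taxa}")
    k = model.k_model
    if include_branch_lengths:
        k += 2 * n_taxa - 3
    return k


def build_rate_matrix(
    model: SubstitutionModel | str,
    exchangeabilities=(),
    freqs=None,
) -> RateMatrix:
    """Construct the normalized reversible rate matrix Q_ij = r_ij * pi_j.

    Parameters
    ----------
    model : SubstitutionModel or str
        Determines the symmetry class and frequency mode.
    exchangeabilities : sequence of float
        One rate per symmetry class.  Either the full set (one per
        distinct class) or the free set (the last class, conventionally
        the GT-containing one, is then fixed at 1).
    freqs : sequence of 4 float, optional
        Stationary frequencies in A,C,G,T order; ignored (forced to 0.25)
        for equal-frequency models.  Required for estimated-frequency
        models.
    """
    if isinstance(model, str):
        model = get_model(model)
    n_classes = model.n_rate_classes
    ex = np.asarray(exchangeabilities, dtype=float)
    if ex.size == n_classes - 1:
        ex = np.append(ex, 1.0)
    elif ex.size != n_classes:
        raise InvalidInputError(
            f"{model.name} needs {n_classes} (or {n_classes - 1}) exchangeability "
            f"values, got {ex.size}"
        )
    if np.any(ex <= 0):
        raise InvalidInputError("exchangeabilities must be positive")

    if model.freq_mode == "equal":
        pi = np.full(4, 0.25)
    else:
        if freqs is None:
            raise InvalidInputError(f"{model.name} requires base frequencies")
        pi = np.asarray(freqs, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0):
            raise InvalidInputError("freqs must be 4 positive values")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise InvalidInputError("freqs must sum to 1")
        pi = pi / pi.sum()

    class_of = [int(c) for c in model.symmetry_class]
    Q = np.zeros((4, 4))
    for pair_idx, (i, j) in enumerate(_PAIR_INDEX):
        r = ex[class_of[pair_idx]]
        Q[i, j] = r * pi[j]
        Q[j, i] = r * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    beta = -(pi * np.diag(Q)).sum()
    if beta <= 0:
        raise InvalidInputError("rate matrix is not normalizable (all rates zero)")
    return RateMatrix(Q=Q / beta, pi=pi)


def spectral_decomposition(rm: RateMatrix):
    """Eigendecomposition of a reversible Q via its symmetric similarity.

    Returns ``(lam, A, B)`` such that ``P(t) = A @ diag(exp(lam * t)) @ B``
    exactly, for any t >= 0.
    """
    rpi = np.sqrt(rm.pi)
    S = (rm.Q * rpi[:, None]) / rpi[None, :]
    lam, U = np.linalg.eigh((S + S.T) / 2)
    A = U / rpi[:, None]
    B = U.T * rpi[None, :]
    return lam, A, B


def registry_table() -> pd.DataFrame:
    """The registry as a DataFrame (exportable as TSV)."""
    rows = [
        {
            "name": m.name,
            "symmetry_class": m.symmetry_class,
            "freq_mode": m.freq_mode,
            "plus_i": m.plus_i,
            "plus_g": m.plus_g,
            "k_model": m.k_model,
            "rank": _RANK[m.name],
        }
        for m in _REGISTRY
    ]
    return pd.DataFrame(rows)
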