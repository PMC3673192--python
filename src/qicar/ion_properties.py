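"""Metal-ion physicochemical descriptor tables.

The screening models regress disease inference scores on 16 descriptors of
metal ions that are mechanistically tied to reactive-oxygen-species
generation: size and mass (AN, AR, r, rho), redox behaviour (dE0, dIP, Z,
AN/dIP), solubility (logKOH, MP, pKsp of the carbonate), softness (sigma_p),
and bonding tendency (Xm, Xm2r, Z/AR, Z2/r).  This module loads and validates
such tables, derives the four composite descriptors, assigns the s-block /
transition grouping used to stratify every regression, and computes the
descriptor rank-correlation structure.

A bundled table covering the 17 study ions (Li, Na, K, Cs, Mg, Ca, Ba, Mn,
Fe, Co, Ni, Ag, Cu, Zn, Cd, Hg, Pb) is provided; its values are compiled
from standard physical-chemistry handbooks and are a synthetic stand-in, so
the file is named accordingly.  Units: radii in angstroms, density in g/cm3,
potentials in volts, ionization steps in eV, melting points in Celsius;
logKOH, pKsp, sigma_p and Xm are dimensionless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical descriptor column names, in bundled-file order.
DESCRIPTORS: tuple[str, ...] = (
    "AN", "AR", "r", "rho", "dE0", "dIP", "Z", "AN_dIP",
    "logKOH", "MP", "pKspCO3", "sigma_p", "Xm", "Xm2r", "Z_AR", "Z2_r",
)

#: Composite descriptors and the primitives they are built from.
COMPOSITES: dict[str, tuple[str, str]] = {
    "AN_dIP": ("AN", "dIP"),   # atomic number : ionization-potential ratio
    "Xm2r": ("Xm", "r"),       # covalent index, Xm^2 * r
    "Z_AR": ("Z", "AR"),       # ionic charge : atomic radius ratio
    "Z2_r": ("Z", "r"),        # cation polarizing power, Z^2 / r
}

S_BLOCK: frozenset[str] = frozenset({"Li", "Na", "K", "Cs", "Mg", "Ca", "Ba"})
#: Pb is p-block but carries multiple oxidation states, so it is analyzed
#: with the transition ions.
TRANSITION: frozenset[str] = frozenset(
    {"Mn", "Fe", "Co", "Ni", "Ag", "Cu", "Zn", "Cd", "Hg", "Pb"}
)

#: Explicit classification for the held-out extension ions used in model
#: validation; they are outside the 17-ion roster, so the grouping is
#: configuration, not chemistry derived at run time.
EXTENSION_GROUPS: dict[str, str] = {"Al": "transition", "Cr": "transition", "V": "transition"}

_QUANTILE_METHODS = {"linear", "averaged_inverted_cdf", "median_unbiased", "hazen"}


@dataclass(frozen=True)
class MetalIon:
    """An ion identified by element symbol and oxidation state."""

    symbol: str
    charge: int

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be a positive integer, got {self.charge}")

    @property
    def group(self) -> str:
        return assign_group(self)

    def __str__(self) -> str:  # e.g. "Fe(II)"
        numerals = {1: "I", 2: "II", 3: "III", 4: "IV", 5: "V", 6: "VI"}
        return f"{self.symbol}({numerals.get(self.charge, str(self.charge))})"


def assign_group(ion: MetalIon | str, extra: dict[str, str] | None = None) -> str:
    """Return the periodic-block stratum ('s-block' or 'transition') of *ion*.

    Ions outside the 17-ion roster must appear in *extra* (defaults to the
    bundled :data:`EXTENSION_GROUPS` covering Al, Cr and V).
    """
    symbol = ion.symbol if isinstance(ion, MetalIon) else ion
    if symbol in S_BLOCK:
        return "s-block"
    if symbol in TRANSITION:
        return "transition"
    lookup = EXTENSION_GROUPS if extra is None else extra
    if symbol in lookup:
        return lookup[symbol]
    raise KeyError(f"no group classification for ion {symbol!r}")


class PropertyTable:
    """Ions x descriptors table with group labels.

    Thin wrapper over a :class:`pandas.DataFrame` indexed by element symbol
    with a ``charge`` column and one column per descriptor; missing cells are
    NaN.  The wrapper adds domain validation (positivity, composite
    consistency) and the derived operations the screen needs.
    """

    def __init__(self, frame: pd.DataFrame, group_config: dict[str, str] | None = None):
        if frame.empty:
            raise ValueError("no ions: property table is empty")
        if frame.index.duplicated().any():
            dupes = sorted(frame.index[frame.index.duplicated()].unique())
            raise ValueError(f"duplicate ion rows: {dupes}")
        if "charge" not in frame.columns:
            raise ValueError("property table requires a 'charge' column")
        self._df = frame.copy()
        self._group_config = dict(EXTENSION_GROUPS if group_config is None else group_config)
        self._validate()

    # -- basic container protocol -------------------------------------------------
    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def ions(self) -> list[str]:
        return list(self._df.index)

    @property
    def descriptors(self) -> list[str]:
        return [c for c in self._df.columns if c in DESCRIPTORS]

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._df.index

    def group_of(self, symbol: str) -> str:
        return assign_group(symbol, self._group_config)

    @property
    def groups(self) -> pd.Series:
        return pd.Series({ion: self.group_of(ion) for ion in self.ions}, name="group")

    def ions_in_group(self, group: str) -> list[str]:
        return [ion for ion in self.ions if self.group_of(ion) == group]

    def values_of(self, prop: str, ions: list[str] | None = None) -> pd.Series:
        """Descriptor values for *ions* (default: all), missing cells dropped."""
        if prop not in self._df.columns:
            raise KeyError(f"unknown descriptor {prop!r}")
        col = self._df[prop] if ions is None else self._df.loc[list(ions), prop]
        return col.dropna().astype(float)

    # -- validation ---------------------------------------------------------------
    def _validate(self, rel_tol: float = 0.01) -> None:
        df = self._df
        for col in df.columns:
            if col in DESCRIPTORS or col == "charge":
                if not pd.api.types.is_numeric_dtype(df[col]):
                    bad = df[col][pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
                    ion = bad.index[0] if len(bad) else "?"
                    raise ValueError(f"non-numeric value for ion {ion!r} in column {col!r}")
            else:
                logger.warning("ignoring unknown column %r", col)
        if "AN" in df.columns:
            an = df["AN"].dropna()
            if (an <= 0).any() or (an != an.round()).any():
                raise ValueError("AN must be a positive integer")
        for col in ("AR", "r", "rho"):
            if col in df.columns and (df[col].dropna() <= 0).any():
                raise ValueError(f"{col} must be strictly positive")
        self.check_composites(rel_tol=rel_tol)

    def check_composites(self, rel_tol: float = 0.01) -> None:
        """Verify stored composites against values recomputed from primitives."""
        for name, expected in self._recompute_composites().items():
            stored = self._df[name]
            both = stored.notna() & expected.notna()
            if not both.any():
                continue
            rel = ((stored[both] - expected[both]).abs()
                   / expected[both].abs().clip(lower=np.finfo(float).tiny))
            if (rel > rel_tol).any():
                ion = rel.idxmax()
                raise ValueError(
                    f"composite {name!r} inconsistent with primitives for ion "
                    f"{ion!r}: stored {stored[ion]:g}, recomputed {expected[ion]:g}"
                )

    def _recompute_composites(self) -> dict[str, pd.Series]:
        df = self._df
        out: dict[str, pd.Series] = {}
        for name, (a, b) in COMPOSITES.items():
            if name not in df.columns or a not in df.columns or b not in df.columns:
                continue
            if name == "AN_dIP":
                denom = df[b]
                if (denom.dropna() == 0).any():
                    raise ZeroDivisionError("dIP = 0 while deriving AN/dIP")
                out[name] = df[a] / denom
            elif name == "Xm2r":
                out[name] = df[a] ** 2 * df[b]
            elif name == "Z_AR":
                if (df[b].dropna() == 0).any():
                    raise ZeroDivisionError("AR = 0 while deriving Z/AR")
                out[name] = df[a] / df[b]
            elif name == "Z2_r":
                if (df[b].dropna() == 0).any():
                    raise ZeroDivisionError("r = 0 while deriving Z2/r")
                out[name] = df[a] ** 2 / df[b]
        return out

    # -- persistence --------------------------------------------------------------
    def to_csv(self, path) -> None:
        self._df.to_csv(path, index_label="ion")


def load_property_table(path, group_config: dict[str, str] | None = None) -> PropertyTable:
    """Read a delimited ion-descriptor table (CSV or TSV, header required).

    The header must use the canonical abbreviations (``AN``, ``AR``, ``r``,
    ``rho``, ``dE0``, ``dIP``, ``Z``, ``AN_dIP``, ``logKOH``, ``MP``,
    ``pKspCO3``, ``sigma_p``, ``Xm``, ``Xm2r``, ``Z_AR``, ``Z2_r``) plus
    ``ion`` and ``charge``; unknown columns are ignored with a warning and
    empty cells are recorded as missing.
    """
    import csv as _csv
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col="ion")
    except (pd.errors.EmptyDataError, _csv.Error):
        raise ValueError("no ions: property file is empty or unreadable") from None
    if df.empty:
        raise ValueError("no ions: property file has a header but no rows")
    for col in df.columns:
        if col in DESCRIPTORS or col == "charge":
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                raise ValueError(
                    f"non-numeric value for ion {bad.idxmax()!r} in column {col!r}"
                )
            df[col] = coerced
    return PropertyTable(df, group_config=group_config)


def load_study_properties(include_extension: bool = False) -> PropertyTable:
    """Load the bundled 17-ion handbook table (synthetic stand-in).

    With ``include_extension=True`` the Al(III)/Cr(VI)/V(V) rows used for
    held-out validation are appended.
    """
    pkg = resources.files("qicar") / "data"
    with resources.as_file(pkg / "study_properties_synthetic.csv") as p:
        table = load_property_table(p)
    if include_extension:
        with resources.as_file(pkg / "extension_properties_synthetic.csv") as p:
            ext = load_property_table(p)
        merged = pd.concat([table.frame, ext.frame])
        return PropertyTable(merged)
    return table


def derive_composites(table: PropertyTable) -> PropertyTable:
    """Fill absent composite descriptors from their primitives.

    Present values are never overwritten — consistency with the primitives is
    checked (at the table's 1% relative tolerance), not repaired.  Division by
    a zero primitive raises.
    """
    df = table.frame.copy()
    for name in COMPOSITES:
        if name not in df.columns:
            df[name] = np.nan
    recomputed = PropertyTable(df)._recompute_composites()
    for name, values in recomputed.items():
        absent = df[name].isna() & values.notna()
        df.loc[absent, name] = values[absent]
    return PropertyTable(df, group_config=table._group_config)


def iqr_of_property(values, method: str = "linear") -> float:
    """Interquartile range Q3 - Q1 of a descriptor distribution.

    *method* selects the quantile convention (any accepted by
    :func:`numpy.quantile`; the default is linear interpolation between order
    statistics, the common "type 7" rule).  Requires at least two finite
    values.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError(f"IQR needs at least 2 finite values, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method=method)
    return float(q3 - q1)


def spearman_property_matrix(table: PropertyTable, min_periods: int = 3) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlations among all descriptors.

    Ties get average ranks.  Pairs with fewer than *min_periods* jointly
    observed ions, or involving a zero-variance column, are NaN (undefined);
    the diagonal is exactly 1 wherever the descriptor has any data.
    """
    df = table.frame[table.descriptors].astype(float)
    corr = df.corr(method="spearman", min_periods=min_periods)
    for prop in corr.columns:
        if df[prop].notna().any():
            corr.loc[prop, prop] = 1.0
    return corr
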