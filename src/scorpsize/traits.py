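"""Trait tables: individual records, species means, log transforms.

The trait vocabulary is the closed set of eight linear measurements used for
buthid scorpions: total length (toL), carapace length (carL), chela length and
width (cheL, cheW), length and width of metasomal segment V (met5L, met5W),
and telson length and width (teL, teW).  All measurements are in millimetres;
analyses run on natural-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

TRAITS: tuple[str, ...] = (
    "toL", "carL", "cheL", "cheW", "met5L", "met5W", "teL", "teW",
)
SEXES: tuple[str, str] = ("female", "male")

#: the six traits that are never used as a body-size response
PREDICTOR_ONLY_TRAITS: tuple[str, ...] = (
    "cheL", "cheW", "met5L", "met5W", "teL", "teW",
)

_CANONICAL = {t.lower(): t for t in TRAITS}


def canonical_trait(name: str) -> str:
    """Map a case-insensitive trait name onto the closed vocabulary."""
    try:
        return _CANONICAL[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown trait {name!r}; expected one of {sorted(_CANONICAL)}"
        ) from None


@dataclass
class TraitMatrix:
    """Species x trait means, one row per species x sex, NaN = missing.

    ``data`` is indexed by a (species, sex) MultiIndex with trait columns;
    ``scale`` is ``"mm"`` (raw millimetres, all values positive) or ``"log"``
    (natural log of mm).  The two representations interconvert exactly via
    :meth:`to_log` / :meth:`to_mm`.
    """

    data: pd.DataFrame
    scale: str = "mm"

    def __post_init__(self):
        if self.scale not in ("mm", "log"):
            raise ValueError(f"scale must be 'mm' or 'log', got {self.scale!r}")
        df = self.data
        if not isinstance(df.index, pd.MultiIndex) or df.index.nlevels != 2:
            raise ValueError("data must have a (species, sex) MultiIndex")
        df.index = df.index.set_names(["species", "sex"])
        bad_sex = set(df.index.get_level_values("sex")) - set(SEXES)
        if bad_sex:
            raise ValueError(f"unknown sex labels: {sorted(bad_sex)}")
        unknown = [c for c in df.columns if c not in TRAITS]
        if unknown:
            raise ValueError(f"unknown trait columns: {unknown}")
        df.columns = pd.Index(df.columns, name="trait")
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise ValueError(f"duplicate species x sex rows: {dups}")
        if self.scale == "mm":
            vals = df.to_numpy(dtype=float)
            if np.any(vals[~np.isnan(vals)] <= 0):
                raise ValueError("mm trait values must be positive")

    # ----------------------------------------------------------- basics

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.data.index.get_level_values("species")))

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness mask, True exactly where a value is absent."""
        return self.data.isna()

    def sex_table(self, sex: str) -> pd.DataFrame:
        """The species x trait table for one sex."""
        if sex not in SEXES:
            raise ValueError(f"unknown sex {sex!r}")
        return self.data.xs(sex, level="sex")

    def copy(self) -> "TraitMatrix":
        return TraitMatrix(self.data.copy(), scale=self.scale)

    # ------------------------------------------------------- transforms

    def to_log(self) -> "TraitMatrix":
        if self.scale == "log":
            raise ValueError("matrix is already on log scale")
        return TraitMatrix(np.log(self.data), scale="log")

    def to_mm(self) -> "TraitMatrix":
        if self.scale == "mm":
            raise ValueError("matrix is already on mm scale")
        return TraitMatrix(np.exp(self.data), scale="mm")

    # ---------------------------------------------------------- reports

    def missingness_report(self) -> pd.DataFrame:
        """Fraction of missing cells per trait and sex."""
        out = {}
        for sex in SEXES:
            try:
                tab = self.sex_table(sex)
            except KeyError:
                continue
            out[sex] = tab.isna().mean(axis=0)
        return pd.DataFrame(out)

    # -------------------------------------------------------------- I/O

    def to_csv(self, path) -> None:
        self.data.reset_index().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, scale: str = "mm") -> "TraitMatrix":
        df = pd.read_csv(path)
        if not {"species", "sex"} <= set(df.columns):
            raise ValueError("wide trait CSV needs 'species' and 'sex' columns")
        df = df.set_index(["species", "sex"])
        df.columns = [canonical_trait(c) for c in df.columns]
        return cls(df.astype(float), scale=scale)


def species_means(records: pd.DataFrame) -> TraitMatrix:
    """Aggregate individual measurements into per-species, per-sex means.

    ``records`` is long format with columns species, sex, trait, value_mm (one
    row per measured individual).  Means are arithmetic means of the raw mm
    values; species x sex x trait cells with no records come out missing.
    """
    required = {"species", "sex", "trait", "value_mm"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rec = records.copy()
    rec["trait"] = rec["trait"].map(canonical_trait)
    bad = rec.index[~(rec["value_mm"] > 0)]
    if len(bad):
        raise ValueError(f"nonpositive value_mm at rows {list(bad[:5])}")
    wide = (
        rec.groupby(["species", "sex", "trait"], sort=True)["value_mm"]
        .mean()
        .unstack("trait")
    )
    wide = wide.reindex(columns=[t for t in TRAITS if t in wide.columns])
    return TraitMatrix(wide, scale="mm")


def read_individuals(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["trait"] = df["trait"].map(canonical_trait)
    return df


def write_individuals(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)
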