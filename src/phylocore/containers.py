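"""Core in-memory containers: sequences, abundance tables, traits, niches."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_ALPHABET = "ACGT"
_BYTE = {c: i for i, c in enumerate(_ALPHABET)}


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


class SequenceSet:
    """An ordered collection of equal-length ungapped nucleotide sequences.

    Sequences are stored as a dense uint8 matrix (A,C,G,T -> 0..3), which is
    what pairwise-identity computation and Jukes-Cantor evolution consume.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValidationError("empty sequence set")
        ids = list(sequences)
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate sequence ids")
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValidationError(f"sequences have unequal lengths: {sorted(lengths)}")
        self.ids: list[str] = ids
        self.length: int = lengths.pop()
        if self.length == 0:
            raise ValidationError("zero-length sequences")
        mat = np.empty((len(ids), self.length), dtype=np.uint8)
        for i, sid in enumerate(ids):
            seq = sequences[sid].upper()
            try:
                mat[i] = [_BYTE[c] for c in seq]
            except KeyError as exc:
                raise ValidationError(
                    f"sequence {sid!r} contains non-ACGT character {exc.args[0]!r}"
                ) from None
        self.matrix: np.ndarray = mat

    @classmethod
    def from_matrix(cls, ids: list[str], matrix: np.ndarray) -> "SequenceSet":
        obj = cls.__new__(cls)
        obj.ids = list(ids)
        obj.matrix = np.asarray(matrix, dtype=np.uint8)
        obj.length = obj.matrix.shape[1]
        if len(obj.ids) != obj.matrix.shape[0]:
            raise ValidationError("ids/matrix shape mismatch")
        return obj

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, sid: str) -> bool:
        return sid in set(self.ids)

    def __getitem__(self, sid: str) -> str:
        i = self.ids.index(sid)
        return "".join(_ALPHABET[b] for b in self.matrix[i])

    def to_dict(self) -> dict[str, str]:
        return {sid: self[sid] for sid in self.ids}

    def subset(self, ids: list[str]) -> "SequenceSet":
        index = {sid: i for i, sid in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sequence ids: {missing}")
        rows = [index[s] for s in ids]
        return SequenceSet.from_matrix(list(ids), self.matrix[rows])


class AbundanceTable:
    """A taxa x samples table of non-negative integer counts.

    Rows are taxa, columns are samples (the on-disk TSV layout). Column sums
    are the per-sample sequencing depths.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.empty:
            raise ValidationError("empty abundance table")
        if counts.index.has_duplicates:
            raise ValidationError("duplicate taxon ids")
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate sample ids")
        arr = counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValidationError("counts must be integers")
            arr = arr.astype(np.int64)
        if (arr < 0).any():
            bad = counts.index[np.where(arr < 0)[0][0]]
            raise ValidationError(f"negative count for taxon {bad!r}")
        self.df = pd.DataFrame(
            arr.astype(np.int64), index=counts.index.astype(str), columns=counts.columns.astype(str)
        )

    @property
    def taxa(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def depths(self) -> pd.Series:
        return self.df.sum(axis=0)

    def relative(self) -> pd.DataFrame:
        depths = self.depths
        if (depths == 0).any():
            bad = list(depths.index[depths == 0])
            raise ValidationError(f"all-zero samples: {bad}")
        return self.df / depths

    def presence(self) -> pd.DataFrame:
        return self.df > 0

    def occupancy(self) -> pd.Series:
        """Per-taxon fraction of samples with at least one read."""
        return (self.df > 0).mean(axis=1)

    def mean_relative(self) -> pd.Series:
        return self.relative().mean(axis=1)

    def subset_samples(self, samples: list[str]) -> "AbundanceTable":
        missing = [s for s in samples if s not in self.df.columns]
        if missing:
            raise ValidationError(f"unknown samples: {missing}")
        return AbundanceTable(self.df[list(samples)])

    def drop_taxa(self, taxa: list[str]) -> "AbundanceTable":
        keep = [t for t in self.taxa if t not in set(taxa)]
        return AbundanceTable(self.df.loc[keep])

    def trim_zero_taxa(self) -> "AbundanceTable":
        keep = self.df.sum(axis=1) > 0
        return AbundanceTable(self.df.loc[keep])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AbundanceTable) and self.df.equals(other.df)


TRAIT_ORIGINS = ("branch_conserved", "convergent", "hgt")

_TRAIT_COLUMNS = ["species", "trait_id", "function_id", "origin", "origin_branch"]


class TraitTable:
    """Species x trait incidence with per-trait origin annotation.

    One row per (species, trait) pair; ``origin`` records how the trait arose
    (conserved on a branch, convergent, or horizontal transfer) and
    ``origin_branch`` the branch it emerged on (the donor lineage for HGT).
    """

    def __init__(self, records: pd.DataFrame):
        missing = [c for c in _TRAIT_COLUMNS if c not in records.columns]
        if missing:
            raise ValidationError(f"trait table missing columns: {missing}")
        df = records[_TRAIT_COLUMNS].reset_index(drop=True).astype(str)
        if df.duplicated(subset=["species", "trait_id"]).any():
            raise ValidationError("duplicate (species, trait_id) pair")
        bad = set(df["origin"]) - set(TRAIT_ORIGINS)
        if bad:
            raise ValidationError(f"unknown trait origins: {sorted(bad)}")
        self.df = df

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    @property
    def trait_ids(self) -> list[str]:
        return sorted(self.df["trait_id"].unique())

    def traits_of(self, species: str) -> set[str]:
        return set(self.df.loc[self.df["species"] == species, "trait_id"])

    def functions_of(self, species: str) -> set[str]:
        return set(self.df.loc[self.df["species"] == species, "function_id"])

    def species_with_trait(self, trait_id: str) -> set[str]:
        return set(self.df.loc[self.df["trait_id"] == trait_id, "species"])

    def species_with_function(self, function_id: str) -> set[str]:
        return set(self.df.loc[self.df["function_id"] == function_id, "species"])

    def covering(self, required: set[str]) -> list[str]:
        """Species carrying every required id (trait ids or function ids)."""
        out = []
        for sp in self.species:
            have = self.traits_of(sp) | self.functions_of(sp)
            if set(required) <= have:
                out.append(sp)
        return sorted(out)


@dataclass(frozen=True)
class NicheSpec:
    """What it takes to occupy a niche, plus optional selective structure.

    required_traits may name trait ids or function ids (a "colour"); species
    covering all of them are eligible. ``advantage`` maps species to fitness
    multipliers (>0, default 1). ``gradient`` (one scalar per sample) with
    per-species ``optima`` imposes sample-specific Gaussian filtering of
    width ``gradient_sd``.
    """

    required_traits: frozenset[str]
    advantage: dict[str, float] = field(default_factory=dict)
    stabilized: dict[str, float] = field(default_factory=dict)
    gradient: tuple[float, ...] | None = None
    optima: dict[str, float] | None = None
    gradient_sd: float = 0.15

    def __post_init__(self) -> None:
        if not self.required_traits:
            raise ValidationError("required_traits must be nonempty")
        for sp, w in self.advantage.items():
            if not w > 0:
                raise ValidationError(f"fitness multiplier for {sp!r} must be > 0")
        for sp, c in self.stabilized.items():
            if not c > 0:
                raise ValidationError(f"stabilization multiplier for {sp!r} must be > 0")
        if self.gradient is not None and self.optima is None:
            raise ValidationError("a gradient requires per-species optima")
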