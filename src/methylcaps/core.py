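"""Core data containers and delimited-text I/O.

The universal input is a :class:`MethylationArray`: a samples x CpGs matrix of
beta values (fraction of methylated signal at each CpG, in [0, 1]) paired with
a phenotype table mapping each sample to a class label and optional covariates.
CpGs are grouped into named *capsules* (genes, island contexts, genomic bins,
gene sets) by a :class:`CapsuleMap`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationArray",
    "CapsuleMap",
    "RunConfig",
    "ValidationError",
    "load_methylation_array",
    "save_methylation_array",
    "load_capsule_map",
    "save_capsule_map",
]


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


@dataclass
class MethylationArray:
    """Beta-value matrix (samples x CpGs) plus aligned phenotype table.

    Parameters
    ----------
    beta
        DataFrame with unique sample ids as index and unique CpG ids as
        columns; every value must lie in [0, 1] and be non-missing.
    pheno
        DataFrame indexed by the same sample ids; the class label lives in
        ``label_col`` (default ``"label"``). Extra columns are carried as
        pass-through covariates and are not used by the models.
    """

    beta: pd.DataFrame
    pheno: pd.DataFrame
    label_col: str = "label"

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        beta, pheno = self.beta, self.pheno
        if beta.index.has_duplicates:
            raise ValidationError("duplicate sample ids in beta matrix")
        if beta.columns.has_duplicates:
            raise ValidationError("duplicate CpG ids in beta matrix")
        if pheno.index.has_duplicates:
            raise ValidationError("duplicate sample ids in phenotype table")
        if list(beta.index) != list(pheno.index):
            missing = set(beta.index).symmetric_difference(pheno.index)
            raise ValidationError(
                f"sample ids differ between beta and pheno (mismatch: {sorted(missing)[:5]})"
            )
        if self.label_col not in pheno.columns:
            raise ValidationError(f"phenotype table lacks label column {self.label_col!r}")
        vals = beta.to_numpy(dtype=float)
        if np.isnan(vals).any():
            i, j = np.argwhere(np.isnan(vals))[0]
            raise ValidationError(
                f"missing beta value at sample {beta.index[i]!r}, CpG {beta.columns[j]!r}"
            )
        bad = (vals < 0.0) | (vals > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] at sample "
                f"{beta.index[i]!r}, CpG {beta.columns[j]!r}"
            )

    # -- convenience --------------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.beta.index)

    @property
    def cpgs(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def labels(self) -> pd.Series:
        return self.pheno[self.label_col]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationArray":
        ids = list(sample_ids)
        return MethylationArray(
            self.beta.loc[ids], self.pheno.loc[ids], label_col=self.label_col
        )

    def subset_cpgs(self, cpg_ids: Sequence[str]) -> "MethylationArray":
        ids = list(cpg_ids)
        missing = [c for c in ids if c not in self.beta.columns]
        if missing:
            raise KeyError(f"CpGs not present in array: {missing[:5]}")
        return MethylationArray(
            self.beta.loc[:, ids], self.pheno, label_col=self.label_col
        )


@dataclass
class CapsuleMap:
    """Named grouping of CpGs into capsules.

    ``capsules`` maps a capsule name to an ordered list of CpG ids. A CpG may
    belong to several capsules. ``d[j]`` is the CpG count of capsule ``j``.
    """

    capsules: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, cpgs in self.capsules.items():
            if not name:
                raise ValidationError("empty capsule name")
            if any(not c for c in cpgs):
                raise ValidationError(f"capsule {name!r} lists an empty CpG id")
            if len(set(cpgs)) != len(cpgs):
                # collapse duplicates, keep first occurrence order
                seen: dict[str, None] = {}
                for c in cpgs:
                    seen.setdefault(c, None)
                warnings.warn(f"duplicate CpGs in capsule {name!r} collapsed")
                self.capsules[name] = list(seen)

    @property
    def d(self) -> dict[str, int]:
        """Per-capsule CpG counts ``d_j``."""
        return {name: len(cpgs) for name, cpgs in self.capsules.items()}

    @property
    def names(self) -> list[str]:
        return list(self.capsules)

    def __len__(self) -> int:
        return len(self.capsules)

    def all_cpgs(self) -> list[str]:
        """Unique CpGs across all capsules, in first-appearance order."""
        seen: dict[str, None] = {}
        for cpgs in self.capsules.values():
            for c in cpgs:
                seen.setdefault(c, None)
        return list(seen)


@dataclass
class RunConfig:
    """Plumbing configuration shared by training entry points."""

    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    hyperparameters: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        fr = self.split_fractions
        if any(f <= 0 for f in fr):
            raise ValidationError("split fractions must be positive")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValidationError(f"split fractions must sum to 1, got {sum(fr)}")


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_methylation_array(
    beta_path: str | Path, pheno_path: str | Path, label_col: str = "label"
) -> MethylationArray:
    """Read beta and phenotype tables (TSV, or CSV by extension).

    The beta header row names CpGs and the first column names samples; the
    phenotype table is indexed by the same sample ids. Validation errors name
    the offending cell or sample.
    """
    beta_path, pheno_path = Path(beta_path), Path(pheno_path)
    beta = pd.read_csv(beta_path, sep=_sep_for(beta_path), index_col=0)
    pheno = pd.read_csv(pheno_path, sep=_sep_for(pheno_path), index_col=0)
    beta.index = beta.index.astype(str)
    pheno.index = pheno.index.astype(str)
    pheno = pheno.reindex(beta.index) if set(pheno.index) == set(beta.index) else pheno
    return MethylationArray(beta, pheno, label_col=label_col)


def save_methylation_array(
    array: MethylationArray, beta_path: str | Path, pheno_path: str | Path
) -> None:
    beta_path, pheno_path = Path(beta_path), Path(pheno_path)
    array.beta.to_csv(beta_path, sep=_sep_for(beta_path))
    array.pheno.to_csv(pheno_path, sep=_sep_for(pheno_path))


def save_capsule_map(cmap: CapsuleMap, path: str | Path) -> None:
    """Write a capsule map as a two-column TSV (capsule, cpg) with header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("capsule\tcpg\n")
        for name, cpgs in cmap.capsules.items():
            for c in cpgs:
                fh.write(f"{name}\t{c}\n")


def load_capsule_map(path: str | Path) -> CapsuleMap:
    """Read a two-column (capsule, cpg) TSV; duplicate pairs collapse with a warning."""
    path = Path(path)
    capsules: dict[str, list[str]] = {}
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        header = fh.readline()
        if header and not header.lower().startswith("capsule"):
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                name, cpg = line.split("\t")
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: expected 2 tab-separated fields") from exc
            if (name, cpg) in pairs:
                warnings.warn(f"duplicate (capsule, CpG) pair ({name}, {cpg}) collapsed")
                continue
            pairs.add((name, cpg))
            capsules.setdefault(name, []).append(cpg)
    return CapsuleMap(capsules)
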