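"""Synthetic beta-value datasets with capsule-coherent class signal.

Real array data show a bimodal beta-value distribution: most CpGs sit near 0
(unmethylated) or near 1 (methylated), with few intermediate sites. The
generator emulates this by drawing each CpG's latent mean from a two-component
Beta mixture and sampling per-sample values from a Beta distribution around
that mean (concentration ``dispersion``).

Class signal is *capsule-coherent*: a designated subset of "signal" capsules
carries a class-conditional shift of the latent mean. Each class has a
direction (+1/-1) per signal capsule and the class means sit at
``base -/+ effect_size/2``, so the between-class mean gap at a signal CpG is
``effect_size`` (in beta-fraction units). Signal-capsule base means are drawn
from a mid-range interval so the shifted means stay inside (0, 1); non-signal
CpGs are identically distributed across classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CapsuleMap, MethylationArray, ValidationError

__all__ = ["SimulationSpec", "SimulationTruth", "simulate_dataset", "make_annotation_fixture"]


@dataclass
class SimulationSpec:
    """Study conditions for one simulated dataset.

    Defaults mirror the synthetic classification setting used throughout the
    test suite: 4 classes, 20 capsules of 10 CpGs each, 5 signal capsules,
    effect size 0.3, 150 samples per class.
    """

    n_samples_per_class: int = 150
    n_classes: int = 4
    capsule_sizes: tuple[int, ...] | None = None  # default: 20 capsules of 10
    n_signal_capsules: int = 5
    effect_size: float = 0.3  # between-class mean-beta gap at signal CpGs
    #: Beta shape pairs for the unmethylated / methylated background modes
    unmethylated_mode: tuple[float, float] = (2.0, 8.0)
    methylated_mode: tuple[float, float] = (8.0, 2.0)
    dispersion: float = 50.0  # Beta concentration of per-sample noise
    signal_mean_range: tuple[float, float] = (0.3, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capsule_sizes is None:
            self.capsule_sizes = tuple([10] * 20)
        if not (0.0 <= self.effect_size < 1.0):
            raise ValidationError("effect_size must lie in [0, 1)")
        for a, b in (self.unmethylated_mode, self.methylated_mode):
            if a <= 0 or b <= 0:
                raise ValidationError("Beta shape parameters must be positive")
        if self.n_signal_capsules > len(self.capsule_sizes):
            raise ValidationError("n_signal_capsules exceeds the number of capsules")
        lo, hi = self.signal_mean_range
        if lo - self.effect_size / 2 <= 0.0 or hi + self.effect_size / 2 >= 1.0:
            raise ValidationError(
                f"infeasible shift: signal means in {self.signal_mean_range} "
                f"+/- {self.effect_size / 2} leave (0, 1)"
            )


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    signal_capsules: list[str]
    #: per-class direction of shift, classes x signal capsules, entries +/-1
    directions: pd.DataFrame = field(repr=False)
    #: latent class-conditional means, (classes x CpGs)
    cpg_means: pd.DataFrame = field(repr=False)


def _class_directions(n_classes: int, n_signal: int) -> np.ndarray:
    """Deterministic +/-1 codewords, pairwise distinct across classes.

    Column ``s`` alternates sign with period ``2**(s+1)`` over the class
    index, so the first ``ceil(log2 n_classes)`` signal capsules already
    separate all classes; later columns repeat the pattern.
    """
    n_bits = max(1, int(np.ceil(np.log2(max(n_classes, 2)))))
    dirs = np.empty((n_classes, n_signal), dtype=float)
    for s in range(n_signal):
        bit = s % n_bits
        for c in range(n_classes):
            dirs[c, s] = 1.0 if (c >> bit) & 1 == 0 else -1.0
    return dirs


def simulate_dataset(
    spec: SimulationSpec,
) -> tuple[MethylationArray, CapsuleMap, SimulationTruth]:
    """Draw one dataset; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.capsule_sizes
    n_caps = len(sizes)
    n_cpgs = int(sum(sizes))
    n_samples = spec.n_samples_per_class * spec.n_classes

    cap_names = [f"CAP{j:03d}" for j in range(n_caps)]
    cpg_names: list[str] = []
    cap_of_cpg: list[int] = []
    capsules: dict[str, list[str]] = {}
    k = 0
    for j, size in enumerate(sizes):
        members = [f"cg{k + i:06d}" for i in range(size)]
        capsules[cap_names[j]] = members
        cpg_names.extend(members)
        cap_of_cpg.extend([j] * size)
        k += size
    cap_of_cpg_arr = np.asarray(cap_of_cpg)

    signal_caps = sorted(rng.choice(n_caps, size=spec.n_signal_capsules, replace=False))
    is_signal_cap = np.zeros(n_caps, dtype=bool)
    is_signal_cap[signal_caps] = True
    signal_col = {cap: s for s, cap in enumerate(signal_caps)}

    # background latent means: bimodal Beta mixture
    mode_choice = rng.random(n_cpgs) < 0.5
    a_u, b_u = spec.unmethylated_mode
    a_m, b_m = spec.methylated_mode
    base = np.where(mode_choice, rng.beta(a_u, b_u, n_cpgs), rng.beta(a_m, b_m, n_cpgs))
    # signal CpGs: mid-range base means so both shifted means stay in (0, 1)
    lo, hi = spec.signal_mean_range
    sig_mask = is_signal_cap[cap_of_cpg_arr]
    base[sig_mask] = rng.uniform(lo, hi, int(sig_mask.sum()))

    dirs = _class_directions(spec.n_classes, spec.n_signal_capsules)
    means = np.tile(base, (spec.n_classes, 1))
    for idx in np.flatnonzero(sig_mask):
        s = signal_col[cap_of_cpg_arr[idx]]
        means[:, idx] = base[idx] + dirs[:, s] * spec.effect_size / 2.0
    if (means <= 0).any() or (means >= 1).any():
        raise ValidationError("infeasible shift: a class-conditional mean leaves (0, 1)")

    labels = np.repeat(np.arange(spec.n_classes), spec.n_samples_per_class)
    mu = means[labels]  # samples x CpGs
    nu = spec.dispersion
    beta_vals = rng.beta(mu * nu, (1.0 - mu) * nu)
    beta_vals = np.clip(beta_vals, 0.0, 1.0)

    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    beta = pd.DataFrame(beta_vals, index=sample_ids, columns=cpg_names)
    pheno = pd.DataFrame({"label": [f"class{c}" for c in labels]}, index=sample_ids)

    truth = SimulationTruth(
        signal_capsules=[cap_names[j] for j in signal_caps],
        directions=pd.DataFrame(
            dirs,
            index=[f"class{c}" for c in range(spec.n_classes)],
            columns=[cap_names[j] for j in signal_caps],
        ),
        cpg_means=pd.DataFrame(
            means, index=[f"class{c}" for c in range(spec.n_classes)], columns=cpg_names
        ),
    )
    return MethylationArray(beta, pheno), CapsuleMap(capsules), truth


def make_annotation_fixture() -> pd.DataFrame:
    """Small deterministic Illumina-dialect annotation table.

    Exercises multi-gene composite fields, every island-relation category,
    TSS200/TSS1500/Body gene groups, and genomic coordinates that fit the
    chromosome sizes ``{"chr1": 2000, "chr2": 1500}``.
    """
    rows = [
        # cpg, genes, groups, island relation, chrom, pos
        ("cg0001", "GENEA", "TSS200", "Island", "chr1", 100),
        ("cg0002", "GENEA;GENEB", "TSS1500;Body", "N_Shore", "chr1", 350),
        ("cg0003", "GENEB", "Body", "S_Shore", "chr1", 700),
        ("cg0004", "GENEC", "TSS200", "N_Shelf", "chr1", 1200),
        ("cg0005", "GENEC;GENEA", "Body;TSS1500", "S_Shelf", "chr1", 1850),
        ("cg0006", "GENED", "TSS1500", "OpenSea", "chr2", 40),
        ("cg0007", "GENED", "Body", "Island", "chr2", 600),
        ("cg0008", "", "", "OpenSea", "chr2", 1100),
        ("cg0009", "GENEB;GENEB", "Body;Body", "Island", "chr2", 1400),
    ]
    ann = pd.DataFrame(
        rows,
        columns=[
            "cpg",
            "UCSC_RefGene_Name",
            "UCSC_RefGene_Group",
            "Relation_to_UCSC_CpG_Island",
            "chrom",
            "pos",
        ],
    ).set_index("cpg")
    ann.loc[ann["UCSC_RefGene_Name"] == "", "UCSC_RefGene_Name"] = np.nan
    ann.loc[ann["UCSC_RefGene_Group"] == "", "UCSC_RefGene_Group"] = np.nan
    return ann


#: chromosome sizes matching :func:`make_annotation_fixture`
FIXTURE_CHROM_SIZES = {"chr1": 2000, "chr2": 1500}
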