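"""Haplodiploid *Nasonia* cross simulation and the three-locus clefting model.

*Nasonia* males are haploid: a virgin F1 hybrid female produces broods of
recombinant haploid F2 males, exposing recessive and epistatic interactions
directly. Facial midline clefting in hybrids is governed by an epistatic
(Dobzhansky-Muller type) interaction among regions on chromosomes 2, 4 and 5,
here modeled as three unlinked biallelic loci ``cleft2``, ``cleft4``,
``cleft5`` with allele origins Nv (*N. vitripennis*), Ng (*N. giraulti*) or
Nl (*N. longicornis*).

Penetrance rules (haploid F2 males, base rate p = 0.25):

* cleft5 = Nv and (cleft2 = Ng or cleft4 = Ng)   -> p
* cleft5 = Ng and cleft2 = cleft4 = Nv           -> p
* all three loci Nv (hybrid-background effect)   -> p
* cleft5 = Ng otherwise: clefting fully suppressed.

Nl alleles act Ng-like in these rules (the incompatibility alleles predate
the Ng/Nl split), which makes clefting impossible in Nl x Ng crosses, as
observed. The interactions are recessive: diploids heterozygous at any rule
locus never cleft (F1 diploid males and F1 hybrid females are normal). The
2C-Cli introgression line (Ng cleft2 region homozygous in an Nv background)
clefts with complete penetrance in both sexes and overrides the rules.

Beyond the genotype-driven cleft model, whole F2 cohorts can be drawn in
"empirical" mode from per-cross defect-class tables (cleft, dorso-ventral
asymmetry, lateral asymmetry, multiple defects, miscellaneous, normal),
whose default probabilities are calibration constants taken from the
printed per-cross defect frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "LOCI",
    "DEFECT_CLASSES",
    "Genotype",
    "PenetranceModel",
    "DefectClassTable",
    "DominanceModel",
    "CohortTable",
    "DEFAULT_PENETRANCE",
    "DEFAULT_DEFECT_TABLES",
    "DEFAULT_DOMINANCE",
    "f2_male_genotype",
    "simulate_f2_males",
    "diploid_f1_male",
    "introgression_genotype",
    "clefting_probability",
    "clefting_truth_table",
    "simulate_f2_cohort",
    "diploid_trait_mean",
]

LOCI = ("cleft2", "cleft4", "cleft5")
SPECIES = ("Nv", "Ng", "Nl")
DEFECT_CLASSES = ("cleft", "dv_asym", "lateral_asym", "multi", "misc", "normal")

_CROSS_ALIASES = {
    "ngxnv": "NgxNv", "nvxng": "NgxNv",
    "nlxnv": "NlxNv", "nvxnl": "NlxNv",
    "nlxng": "NlxNg", "ngxnl": "NlxNg",
}


def canonical_cross(label: str) -> str:
    key = label.replace("×", "x").replace("-", "x").replace("_", "x").lower()
    if key not in _CROSS_ALIASES:
        raise ValueError(f"unknown cross label {label!r}; expected one of NgxNv, NlxNv, NlxNg")
    return _CROSS_ALIASES[key]


@dataclass(frozen=True)
class Genotype:
    """Alleles at the three clefting loci, plus ploidy/background/sex.

    ``alleles`` maps locus -> tuple of allele origins: length 1 for haploids,
    2 for diploids. Haploids are male (haplodiploid sex determination).
    """

    alleles: Mapping[str, tuple[str, ...]]
    ploidy: str = "haploid"  # "haploid" | "diploid"
    sex: str = "male"
    background: str = "F2"  # pure | F1 | F2 | introgression-2C-Cli | introgression-wm114

    def __post_init__(self):
        alleles = {loc: tuple(self.alleles[loc]) for loc in LOCI}
        object.__setattr__(self, "alleles", alleles)
        expected = 1 if self.ploidy == "haploid" else 2
        if self.ploidy not in ("haploid", "diploid"):
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        for loc, origins in alleles.items():
            if len(origins) != expected:
                raise ValueError(
                    f"{self.ploidy} genotype needs {expected} allele(s) at {loc}, got {len(origins)}"
                )
            for o in origins:
                if o not in SPECIES:
                    raise ValueError(f"unknown allele origin {o!r} at {loc}")
        if self.ploidy == "haploid" and self.sex != "male":
            raise ValueError("haploid individuals are male in haplodiploids")

    def is_heterozygous(self, locus: str) -> bool:
        origins = self.alleles[locus]
        return len(set(origins)) > 1

    def origin(self, locus: str) -> str:
        """Single effective origin for haploids and homozygous diploids."""
        origins = set(self.alleles[locus])
        if len(origins) != 1:
            raise ValueError(f"locus {locus} is heterozygous; no single origin")
        return next(iter(origins))


@dataclass(frozen=True)
class PenetranceModel:
    """Clefting penetrance: base rate for rule-satisfying genotypes, and the
    recessivity policy for diploids. ``recessive=None`` forces callers to
    choose explicitly before scoring diploid genotypes."""

    p_cleft_base: float = 0.25
    recessive: bool | None = True

    def __post_init__(self):
        if not 0.0 <= self.p_cleft_base <= 1.0:
            raise ValueError("p_cleft_base must be in [0, 1]")


DEFAULT_PENETRANCE = PenetranceModel()


def _ng_like(origin: str) -> bool:
    # Nl alleles behave like Ng in the clefting rules.
    return origin in ("Ng", "Nl")


def clefting_probability(g: Genotype, model: PenetranceModel = DEFAULT_PENETRANCE) -> float:
    """Clefting probability of a genotype under the epistatic rule set."""
    if g.background == "pure":
        return 0.0
    if g.background == "introgression-2C-Cli":
        return 1.0  # fully penetrant line, both sexes
    if g.background == "introgression-wm114":
        return 0.0  # dsx-region introgression; clefting loci are all Nv

    if g.ploidy == "diploid":
        if model.recessive is None:
            raise ValueError(
                "diploid genotype scored without a recessivity policy; "
                "set PenetranceModel.recessive explicitly"
            )
        if model.recessive and any(g.is_heterozygous(loc) for loc in LOCI):
            # Recessive incompatibility: one compatible allele at any rule
            # locus suffices to buffer development (F1 males/females normal).
            return 0.0

    c2, c4, c5 = (g.alleles[loc][0] if not g.is_heterozygous(loc) else None for loc in LOCI)
    if c2 is None or c4 is None or c5 is None:
        # non-recessive diploid policy with heterozygous loci: no rule applies
        return 0.0

    if c5 == "Nv" and (_ng_like(c2) or _ng_like(c4)):
        return model.p_cleft_base
    if _ng_like(c5) and c2 == "Nv" and c4 == "Nv":
        return model.p_cleft_base
    if c2 == c4 == c5 == "Nv" and g.background == "F2":
        # background effect: clefting at the base rate even with all-Nv loci,
        # but only on the recombinant hybrid background
        return model.p_cleft_base
    return 0.0


def clefting_truth_table(
    cross: str = "NgxNv", model: PenetranceModel = DEFAULT_PENETRANCE
) -> pd.DataFrame:
    """Exhaustive table over the 8 equiprobable haploid three-locus patterns.

    Columns: cleft2, cleft4, cleft5, p_cleft. The mixture mean (uniform over
    patterns) is the expected F2 cleft fraction; 5/32 = 0.15625 at the
    default base rate for crosses to Nv.
    """
    a, b = _cross_parents(cross)
    rows = []
    for o2 in (a, b):
        for o4 in (a, b):
            for o5 in (a, b):
                g = Genotype(alleles={"cleft2": (o2,), "cleft4": (o4,), "cleft5": (o5,)},
                             background="F2")
                rows.append({"cleft2": o2, "cleft4": o4, "cleft5": o5,
                             "p_cleft": clefting_probability(g, model)})
    return pd.DataFrame(rows)


def _cross_parents(cross: str) -> tuple[str, str]:
    label = canonical_cross(cross)
    return {"NgxNv": ("Ng", "Nv"), "NlxNv": ("Nl", "Nv"), "NlxNg": ("Nl", "Ng")}[label]


def f2_male_genotype(parents: tuple[str, str], rng: np.random.Generator) -> Genotype:
    """Draw one haploid F2 male from a cross between two parental species.

    The three loci sit on different chromosomes, so allele origins segregate
    independently, each parental origin with probability 1/2. A same-species
    "cross" yields a pure-background genotype (flagged via ``background``).
    """
    a, b = parents
    if a not in SPECIES or b not in SPECIES:
        raise ValueError(f"unknown species in parents {parents!r}")
    if a == b:
        return Genotype(
            alleles={loc: (a,) for loc in LOCI}, background="pure",
        )
    picks = rng.integers(0, 2, size=len(LOCI))
    return Genotype(
        alleles={loc: ((a,) if p == 0 else (b,)) for loc, p in zip(LOCI, picks)},
        background="F2",
    )


def simulate_f2_males(
    parents: tuple[str, str],
    n: int,
    rng: np.random.Generator,
    model: PenetranceModel = DEFAULT_PENETRANCE,
) -> pd.DataFrame:
    """Vectorized draw of ``n`` F2 males with Bernoulli cleft calls.

    Returns a DataFrame with columns cleft2/cleft4/cleft5 (allele origin) and
    ``cleft`` (bool).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    a, b = parents
    if a == b:
        raise ValueError("F2 simulation requires two distinct species")
    origins = np.where(rng.integers(0, 2, size=(n, len(LOCI))) == 0, a, b)
    df = pd.DataFrame(origins, columns=list(LOCI))

    # probability per row via the 8-pattern truth table (exact, no per-row loop)
    truth = clefting_truth_table(cross=f"{a}x{b}", model=model)
    key = truth[list(LOCI)].agg("-".join, axis=1)
    lookup = dict(zip(key, truth["p_cleft"]))
    p = df[list(LOCI)].agg("-".join, axis=1).map(lookup).to_numpy(dtype=float)
    df["p_cleft"] = p
    df["cleft"] = rng.random(n) < p
    return df


def diploid_f1_male(mother: str, father: str) -> Genotype:
    """Diploid F1 hybrid male: heterozygous (maternal, paternal) at every
    locus, deterministic — no recombination or assortment has occurred.

    Produced experimentally by knocking down maternal *transformer* so that
    fertilized (diploid) eggs develop as males.
    """
    if mother not in SPECIES or father not in SPECIES:
        raise ValueError(f"unknown species {mother!r} x {father!r}")
    if mother == father:
        raise ValueError("F1 hybrid requires two distinct species")
    return Genotype(
        alleles={loc: (mother, father) for loc in LOCI},
        ploidy="diploid",
        sex="male",
        background="F1",
    )


def introgression_genotype(line: str, sex: str = "female") -> Genotype:
    """Genotype of a named introgression line.

    2C-Cli: the Ng chromosome-2 clefting region fixed (homozygous, or
    hemizygous in males) in an Nv background; fully penetrant clefting in
    both sexes. wm114: the Ng *dsx* regulatory region on chromosome 4 in an
    Nv background; affects head shape, not the clefting loci.
    """
    if line not in ("introgression-2C-Cli", "introgression-wm114", "2C-Cli", "wm114"):
        raise ValueError(f"unknown introgression line {line!r}")
    line = line if line.startswith("introgression-") else f"introgression-{line}"
    ploidy = "haploid" if sex == "male" else "diploid"
    k = 1 if ploidy == "haploid" else 2
    if line == "introgression-2C-Cli":
        alleles = {"cleft2": ("Ng",) * k, "cleft4": ("Nv",) * k, "cleft5": ("Nv",) * k}
    else:
        alleles = {loc: ("Nv",) * k for loc in LOCI}
    return Genotype(alleles=alleles, ploidy=ploidy, sex=sex, background=line)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DefectClassTable:
    """Per-cross defect-class probabilities (calibration constants)."""

    cross: str
    probs: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "cross", canonical_cross(self.cross))
        probs = {cls: float(self.probs[cls]) for cls in DEFECT_CLASSES}
        object.__setattr__(self, "probs", probs)
        if any(not 0.0 <= p <= 1.0 for p in probs.values()):
            raise ValueError("class probabilities must be in [0, 1]")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class probabilities must sum to 1, got {total}")

    @property
    def p_any_defect(self) -> float:
        return 1.0 - self.probs["normal"]


#: Default per-cross defect-class tables. The totals (88%, 80%, ~20%) and the
#: Nl x Ng breakdown (no clefting, 5% each asymmetry class, 10% misc = half
#: of all defects, no multiples) are printed values; the within-cross splits
#: for the crosses to Nv are set inside the printed ranges (asymmetries
#: ~24-34% each, multiples 10-12%, miscellaneous ~20%).
DEFAULT_DEFECT_TABLES = {
    "NgxNv": DefectClassTable(
        cross="NgxNv",
        probs={"cleft": 0.12, "dv_asym": 0.24, "lateral_asym": 0.24,
               "multi": 0.10, "misc": 0.18, "normal": 0.12},
    ),
    "NlxNv": DefectClassTable(
        cross="NlxNv",
        probs={"cleft": 0.10, "dv_asym": 0.24, "lateral_asym": 0.20,
               "multi": 0.10, "misc": 0.16, "normal": 0.20},
    ),
    "NlxNg": DefectClassTable(
        cross="NlxNg",
        probs={"cleft": 0.00, "dv_asym": 0.05, "lateral_asym": 0.05,
               "multi": 0.00, "misc": 0.10, "normal": 0.80},
    ),
}


@dataclass
class CohortTable:
    """Simulated per-cross defect-class counts."""

    cross: str
    counts: Mapping[str, int]
    n: int
    mode: str
    seed: int | None = None

    def __post_init__(self):
        counts = {cls: int(self.counts.get(cls, 0)) for cls in DEFECT_CLASSES}
        object.__setattr__(self, "counts", counts)
        if sum(counts.values()) != self.n:
            raise ValueError("class counts must sum to cohort size")

    @property
    def fractions(self) -> dict[str, float]:
        return {cls: cnt / self.n for cls, cnt in self.counts.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(DEFECT_CLASSES),
                "count": [self.counts[c] for c in DEFECT_CLASSES],
                "fraction": [self.counts[c] / self.n for c in DEFECT_CLASSES],
            }
        )


def simulate_f2_cohort(
    cross: str,
    n: int,
    rng: np.random.Generator,
    mode: str = "empirical",
    model: PenetranceModel = DEFAULT_PENETRANCE,
    table: DefectClassTable | None = None,
    seed: int | None = None,
) -> CohortTable:
    """Simulate an F2 male cohort.

    ``mode="genotype"``: draw three-locus genotypes and Bernoulli cleft calls
    from the penetrance model (classes are cleft/normal only). ``"empirical"``:
    one multinomial draw from the cross's defect-class table.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    label = canonical_cross(cross)

    if mode == "genotype":
        parents = _cross_parents(label)
        df = simulate_f2_males(parents, n, rng, model=model)
        n_cleft = int(df["cleft"].sum())
        counts = {"cleft": n_cleft, "normal": n - n_cleft}
        return CohortTable(cross=label, counts=counts, n=n, mode=mode, seed=seed)

    if mode == "empirical":
        if table is None:
            table = DEFAULT_DEFECT_TABLES.get(label)
            if table is None:
                raise ValueError(f"no defect-class table for cross {label!r}")
        p = [table.probs[c] for c in DEFECT_CLASSES]
        draw = rng.multinomial(n, p)
        counts = dict(zip(DEFECT_CLASSES, (int(v) for v in draw)))
        return CohortTable(cross=label, counts=counts, n=n, mode=mode, seed=seed)

    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Dominance of head-shape ratios in diploid F1 males
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DominanceModel:
    """Per-ratio dominance weight w toward the Nv parental mean.

    w = 1: Nv-dominant; w = 0: Ng-dominant; w = 0.5: additive. The diploid
    F1 male trait mean is w * mean_Nv + (1 - w) * mean_Ng, always between
    the parental means.
    """

    weights: Mapping[str, float]

    def __post_init__(self):
        weights = dict(self.weights)
        object.__setattr__(self, "weights", weights)
        for name, w in weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"dominance weight for {name} out of [0, 1]: {w}")


#: Defaults follow the observed F1 diploid male phenotypes: OIO/HL
#: indistinguishable from Nv (Nv-dominant); AIO/HL and MHW/HL
#: indistinguishable from Ng (Ng-dominant); MIO/HL and cheek size distinct
#: from both parents (additive / incomplete dominance).
DEFAULT_DOMINANCE = DominanceModel(
    weights={"OIO_HL": 1.0, "AIO_HL": 0.0, "MHW_HL": 0.0, "MIO_HL": 0.5, "FEP_FE": 0.5}
)


def diploid_trait_mean(
    ratio: str,
    parents: tuple[float, float],
    dom: DominanceModel = DEFAULT_DOMINANCE,
) -> float:
    """Expected ratio in diploid F1 males: w * mean_Nv + (1 - w) * mean_Ng."""
    if ratio not in dom.weights:
        raise KeyError(f"no dominance weight for ratio {ratio!r}")
    mean_nv, mean_ng = parents
    w = dom.weights[ratio]
    return w * mean_nv + (1.0 - w) * mean_ng
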