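"""Synthetic specimen generator.

The study's specimen images are not deposited, so every pipeline stage runs
against synthetic data with the statistical structure the analyses assume:

* six species/sex head templates (Nv/Ng/Nl male/female), exactly bilaterally
  symmetric, whose noiseless derived ratios reproduce the qualitative
  orderings of the wild-type comparisons (e.g. Nv males widest, Ng males
  narrow-faced and big-cheeked, Nl males intermediate);
* three separable noise channels — symmetric among-individual shape
  variation, fluctuating asymmetry (FA, independent per side), and
  per-replicate digitizing noise — so asymmetry is attributable by
  construction;
* defect morphs mimicking the hybrid phenotypes (midline cleft furrow,
  one-sided lateral asymmetry, dorso-ventral eye shear, swollen-head
  miscellany);
* appendage (T1 leg, forewing) lengths with side noise that is identical
  across groups: hybrid heads are asymmetric, hybrid appendages are not.

Template coordinates are fictional but dimensioned so head length is ~1
unit. The two FA defaults are frozen calibration constants chosen once so
that the wild-type and F2-hybrid cohorts score ~99.5% and ~93% mean
left-right correlation under the package's symmetry statistic, matching the
reported scale of the real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cross_sim import DEFAULT_DEFECT_TABLES, CohortTable, simulate_f2_cohort
from .landmark_io import (
    DEFAULT_HEAD_SCHEME,
    AppendageLengths,
    LandmarkConfiguration,
    average_replicates,
    write_tps,
)
from .measurements import HeadMeasurements, compute_ratios, measures_from_landmarks

__all__ = [
    "ShapeTemplate",
    "GeneratorConfig",
    "SampledHead",
    "SyntheticStudy",
    "make_templates",
    "hybrid_template",
    "sample_head",
    "sample_appendages",
    "generate_study",
    "FA_SD_WILDTYPE",
    "FA_SD_HYBRID",
]

#: Frozen FA calibration (template units, head length ~ 1). Chosen once so
#: that cohort mean correlation lands at ~99.5 (wild type) and ~93 (F2
#: hybrid) with digitizing sd 0.002 and triplicate averaging.
FA_SD_WILDTYPE = 0.0215
FA_SD_HYBRID = 0.082

# Template geometry: species/sex-specific full widths (head length = 1).
# mhw: maximum head width; oio/mio/aio: interocular distances at the
# ocelli / widest point / antennal sockets; cheek_x: lateral offset of the
# cheek arc (drives FEP).
_PARAMS: dict[tuple[str, str], dict[str, float]] = {
    ("Nv", "male"):   {"mhw": 0.95, "oio": 0.26, "mio": 0.56, "aio": 0.23, "cheek_x": 0.36},
    ("Ng", "male"):   {"mhw": 0.82, "oio": 0.19, "mio": 0.40, "aio": 0.16, "cheek_x": 0.44},
    ("Nl", "male"):   {"mhw": 0.84, "oio": 0.20, "mio": 0.48, "aio": 0.18, "cheek_x": 0.40},
    ("Nv", "female"): {"mhw": 0.88, "oio": 0.25, "mio": 0.48, "aio": 0.22, "cheek_x": 0.33},
    ("Ng", "female"): {"mhw": 0.80, "oio": 0.24, "mio": 0.49, "aio": 0.21, "cheek_x": 0.37},
    ("Nl", "female"): {"mhw": 0.80, "oio": 0.25, "mio": 0.49, "aio": 0.21, "cheek_x": 0.38},
}

AUX_PAIRS = (("head_left", "head_right"),)
AUX_MIDLINE = ("head_top", "head_bottom")


@dataclass(frozen=True)
class ShapeTemplate:
    """Mean head shape for one species/sex: 16 landmarks plus the four head
    outline points (aux) that carry the MHW/HL endpoints."""

    species: str
    sex: str
    coords: np.ndarray  # (16, 2), midline at x = 0
    aux: Mapping[str, np.ndarray]

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        object.__setattr__(
            self, "aux", {k: np.asarray(v, dtype=float) for k, v in self.aux.items()}
        )


def _build_template(species: str, sex: str, p: Mapping[str, float]) -> ShapeTemplate:
    scheme = DEFAULT_HEAD_SCHEME
    half = {k: p[k] / 2.0 for k in ("mhw", "oio", "mio", "aio")}
    eye_arc_x = p["mhw"] / 2.0 - 0.04
    pos = {
        "median-ocellus": (0.0, 0.90),
        "lateral-ocellus-L": (-half["oio"], 0.88),
        "lateral-ocellus-R": (half["oio"], 0.88),
        "eye-top-L": (-0.32, 0.78), "eye-top-R": (0.32, 0.78),
        "eye-bottom-L": (-0.30, 0.25), "eye-bottom-R": (0.30, 0.25),
        "eye-arc-L": (-eye_arc_x, 0.52), "eye-arc-R": (eye_arc_x, 0.52),
        "cheek-arc-L": (-p["cheek_x"], 0.15), "cheek-arc-R": (p["cheek_x"], 0.15),
        "mio-L": (-half["mio"], 0.55), "mio-R": (half["mio"], 0.55),
        "antennal-socket-L": (-half["aio"], 0.35), "antennal-socket-R": (half["aio"], 0.35),
        "mandible-center": (0.0, 0.02),
    }
    coords = np.array([pos[name] for name in scheme.names], dtype=float)
    aux = {
        "head_top": np.array([0.0, 1.0]),
        "head_bottom": np.array([0.0, 0.0]),
        "head_left": np.array([-half["mhw"], 0.5]),
        "head_right": np.array([half["mhw"], 0.5]),
    }
    return ShapeTemplate(species=species, sex=sex, coords=coords, aux=aux)


def make_templates() -> dict[tuple[str, str], ShapeTemplate]:
    """The six parental species/sex templates."""
    return {key: _build_template(key[0], key[1], p) for key, p in _PARAMS.items()}


def hybrid_template() -> ShapeTemplate:
    """F2 hybrid male mean shape: midpoint of the Nv and Ng male templates."""
    templates = make_templates()
    a, b = templates[("Nv", "male")], templates[("Ng", "male")]
    coords = (a.coords + b.coords) / 2.0
    aux = {k: (a.aux[k] + b.aux[k]) / 2.0 for k in a.aux}
    return ShapeTemplate(species="NgxNv-F2", sex="male", coords=coords, aux=aux)


@dataclass
class GeneratorConfig:
    """Generator settings; the defaults are the stated world of the study.

    Cohort sizes follow the study design: 58 wild-type symmetry heads
    (30 Nv / 28 Ng, split evenly by sex), 105 F2 hybrid heads, 72 wild-type
    appendage specimens. Noise SDs are in template units (head length ~ 1);
    appendage lengths in mm.
    """

    seed: int
    n_parental_per_group: int = 20
    wildtype_symmetry_groups: tuple[tuple[str, str, int], ...] = (
        ("Nv", "male", 15), ("Nv", "female", 15), ("Ng", "male", 14), ("Ng", "female", 14),
    )
    n_hybrid_symmetry: int = 105
    f2_cohort_n: int = 500
    n_replicates: int = 3
    ind_sd: float = 0.010
    dig_sd: float = 0.002
    fa_sd_wildtype: float = FA_SD_WILDTYPE
    fa_sd_hybrid: float = FA_SD_HYBRID
    cleft_mag: float = 0.06
    lateral_mag: float = 0.05
    dv_mag: float = 0.05
    misc_mag: float = 0.05
    leg_mean: float = 1.2
    wing_mean: float = 1.5
    appendage_ind_sd: float = 0.04
    side_sd: float = 0.006
    appendage_rep_sd: float = 0.002
    n_appendage_wildtype: int = 72

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("ind_sd", "dig_sd", "fa_sd_wildtype", "fa_sd_hybrid",
                     "cleft_mag", "lateral_mag", "dv_mag", "misc_mag",
                     "appendage_ind_sd", "side_sd", "appendage_rep_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


DEFECT_MORPHS = ("cleft", "dv_asym", "lateral_asym", "multi", "misc")


@dataclass
class SampledHead:
    """One synthetic specimen: averaged configuration, its replicates, the
    individual's head-outline aux points, and the latent truth."""

    config: LandmarkConfiguration
    replicates: list[LandmarkConfiguration]
    aux: dict[str, np.ndarray]
    truth: dict


def _symmetric_field(rng: np.random.Generator, sd: float) -> np.ndarray:
    """Mirror-symmetric deviation field over the 16 landmarks: paired
    landmarks get mirrored (x negated) copies of one draw; midline landmarks
    move only along y."""
    scheme = DEFAULT_HEAD_SCHEME
    dev = np.zeros((16, 2))
    for left, right in scheme.paired:
        d = rng.normal(0.0, sd, size=2)
        dev[scheme.index(left)] = d
        dev[scheme.index(right)] = (-d[0], d[1])
    for label in scheme.midline:
        dev[scheme.index(label), 1] = rng.normal(0.0, sd)
    return dev


def _apply_defect(coords: np.ndarray, defect: str, cfg: GeneratorConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Defect morphs in the template frame (midline at x = 0)."""
    scheme = DEFAULT_HEAD_SCHEME
    out = coords.copy()

    def idx(label):
        return scheme.index(label)

    def one(kind):
        if kind == "cleft":
            # midline furrow: mandible center pulled up, sockets pinched inward
            out[idx("mandible-center"), 1] += cfg.cleft_mag
            out[idx("antennal-socket-L"), 0] += cfg.cleft_mag / 2
            out[idx("antennal-socket-R"), 0] -= cfg.cleft_mag / 2
        elif kind == "lateral_asym":
            side = "L" if rng.random() < 0.5 else "R"
            sign = -1.0 if side == "L" else 1.0
            out[idx(f"cheek-arc-{side}"), 0] += sign * cfg.lateral_mag
            out[idx(f"eye-arc-{side}"), 0] += sign * cfg.lateral_mag / 2
        elif kind == "dv_asym":
            side = "L" if rng.random() < 0.5 else "R"
            sign = -1.0 if side == "L" else 1.0
            out[idx(f"eye-top-{side}"), 0] += sign * cfg.dv_mag
            out[idx(f"eye-bottom-{side}"), 0] -= sign * cfg.dv_mag
        elif kind == "misc":
            # swollen head: ocellar field pushed dorsally
            for label in ("median-ocellus", "lateral-ocellus-L", "lateral-ocellus-R"):
                out[idx(label), 1] += cfg.misc_mag
        else:
            raise ValueError(f"unknown defect class {kind!r}")

    if defect == "multi":
        one("cleft")
        one("lateral_asym")
    else:
        one(defect)
    return out


def sample_head(
    template: ShapeTemplate,
    rng: np.random.Generator,
    config: GeneratorConfig,
    specimen_id: str,
    fa_sd: float | None = None,
    defect: str | None = None,
    group: str | None = None,
) -> SampledHead:
    """Draw one specimen: symmetric individual deviation + per-side FA +
    optional defect morph, then ``n_replicates`` digitizing replicates,
    landmark-averaged."""
    if defect is not None and defect not in DEFECT_MORPHS:
        raise ValueError(f"unknown defect class {defect!r}")
    fa = config.fa_sd_wildtype if fa_sd is None else fa_sd

    base = template.coords + _symmetric_field(rng, config.ind_sd)
    base = base + rng.normal(0.0, fa, size=base.shape)
    if defect is not None:
        base = _apply_defect(base, defect, config, rng)

    # individual head outline: symmetric deviation only (aux feeds MHW/HL)
    aux_dev_lr = rng.normal(0.0, config.ind_sd, size=2)
    aux_dev_tb = rng.normal(0.0, config.ind_sd, size=2)
    aux = {
        "head_left": template.aux["head_left"] + np.array([-aux_dev_lr[0], aux_dev_lr[1]]),
        "head_right": template.aux["head_right"] + np.array([aux_dev_lr[0], aux_dev_lr[1]]),
        "head_top": template.aux["head_top"] + np.array([0.0, aux_dev_tb[0]]),
        "head_bottom": template.aux["head_bottom"] + np.array([0.0, aux_dev_tb[1]]),
    }

    meta = dict(
        species=template.species, sex=template.sex,
        group=group or f"{template.species}-{template.sex}",
    )
    replicates = [
        LandmarkConfiguration(
            specimen_id=specimen_id,
            coords=base + rng.normal(0.0, config.dig_sd, size=base.shape),
            replicate_index=i,
            **meta,
        )
        for i in range(config.n_replicates)
    ]
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # replicate-count warning for n < 3
        averaged = average_replicates(replicates)
    truth = dict(specimen_id=specimen_id, group=meta["group"], defect=defect or "normal",
                 fa_sd=fa, template=f"{template.species}/{template.sex}")
    return SampledHead(config=averaged, replicates=replicates, aux=aux, truth=truth)


def sample_appendages(
    rng: np.random.Generator,
    config: GeneratorConfig,
    group: str,
    n: int,
    id_prefix: str = "app",
) -> list[AppendageLengths]:
    """Appendage lengths for ``n`` specimens (T1 leg + forewing each).

    Left and right share the individual's mean; the side noise SD is the
    same for every group, hybrids included — appendages are symmetric.
    """
    out = []
    for i in range(n):
        sid = f"{id_prefix}-{group}-{i:03d}"
        for part, mean in (("T1-leg", config.leg_mean), ("forewing", config.wing_mean)):
            indiv = rng.normal(mean, config.appendage_ind_sd)
            sides = {}
            for side in ("left", "right"):
                true_len = indiv + rng.normal(0.0, config.side_sd)
                sides[side] = tuple(
                    true_len + rng.normal(0.0, config.appendage_rep_sd)
                    for _ in range(config.n_replicates)
                )
            out.append(
                AppendageLengths(
                    specimen_id=sid, part=part,
                    left_replicates=sides["left"], right_replicates=sides["right"],
                    group=group,
                )
            )
    return out


@dataclass
class SyntheticStudy:
    """A complete synthetic study bundle plus its latent truth sheet."""

    config: GeneratorConfig
    templates: dict
    parental_heads: list[SampledHead]
    measurements: list[HeadMeasurements]
    wildtype_symmetry: list[LandmarkConfiguration]
    hybrid_symmetry: list[LandmarkConfiguration]
    appendages: list[AppendageLengths]
    cohorts: dict[str, CohortTable]
    truth: pd.DataFrame

    def ratios(self):
        return [compute_ratios(m) for m in self.measurements]

    def write(self, outdir) -> None:
        """Emit the bundle as TPS + CSV text files."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tps([h.config for h in self.parental_heads], outdir / "parental_heads.tps")
        write_tps(self.wildtype_symmetry, outdir / "wildtype_symmetry.tps")
        write_tps(self.hybrid_symmetry, outdir / "hybrid_symmetry.tps")
        pd.DataFrame(
            [
                {"specimen_id": m.specimen_id, "group": m.group, "sex": m.sex,
                 "MHW": m.MHW, "HL": m.HL, "OIO": m.OIO, "MIO": m.MIO,
                 "AIO": m.AIO, "FE": m.FE, "FEP": m.FEP}
                for m in self.measurements
            ]
        ).to_csv(outdir / "measurements.csv", index=False)
        rows = []
        for a in self.appendages:
            for side, reps in (("left", a.left_replicates), ("right", a.right_replicates)):
                for j, length in enumerate(reps):
                    rows.append({"specimen_id": a.specimen_id, "group": a.group,
                                 "part": a.part, "side": side, "replicate": j,
                                 "length": length})
        pd.DataFrame(rows).to_csv(outdir / "appendages.csv", index=False)
        pd.concat(
            [c.to_frame().assign(cross=label) for label, c in self.cohorts.items()],
            ignore_index=True,
        ).to_csv(outdir / "cohorts.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Generate the full synthetic study for a seed.

    Cohorts: six parental groups (measurement pipeline), the 58-head
    wild-type and 105-head hybrid symmetry cohorts, wild-type + hybrid
    appendages, and one empirical-mode F2 defect cohort per cross.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    templates = make_templates()
    hyb = hybrid_template()
    truth_rows: list[dict] = []

    parental_heads: list[SampledHead] = []
    measurements: list[HeadMeasurements] = []
    for (species, sex), template in templates.items():
        for i in range(config.n_parental_per_group):
            head = sample_head(
                template, rng, config,
                specimen_id=f"{species}-{sex}-{i:03d}",
            )
            parental_heads.append(head)
            m = measures_from_landmarks(head.config, aux=head.aux)
            measurements.append(m)
            truth_rows.append({**head.truth, "cohort": "parental"})

    wildtype_symmetry: list[LandmarkConfiguration] = []
    for species, sex, n in config.wildtype_symmetry_groups:
        template = templates[(species, sex)]
        for i in range(n):
            head = sample_head(
                template, rng, config,
                specimen_id=f"sym-{species}-{sex}-{i:03d}",
                fa_sd=config.fa_sd_wildtype,
                group="wildtype",
            )
            wildtype_symmetry.append(head.config)
            truth_rows.append({**head.truth, "cohort": "wildtype_symmetry"})

    hybrid_symmetry: list[LandmarkConfiguration] = []
    for i in range(config.n_hybrid_symmetry):
        head = sample_head(
            hyb, rng, config,
            specimen_id=f"sym-hybrid-{i:03d}",
            fa_sd=config.fa_sd_hybrid,
            group="hybrid",
        )
        hybrid_symmetry.append(head.config)
        truth_rows.append({**head.truth, "cohort": "hybrid_symmetry"})

    appendages: list[AppendageLengths] = []
    n_wt = config.n_appendage_wildtype
    appendages += sample_appendages(rng, config, "Nv", n_wt // 2)
    appendages += sample_appendages(rng, config, "Ng", n_wt - n_wt // 2)
    appendages += sample_appendages(rng, config, "hybrid", config.n_hybrid_symmetry)

    cohorts = {
        label: simulate_f2_cohort(label, config.f2_cohort_n, rng, mode="empirical",
                                  table=table, seed=config.seed)
        for label, table in DEFAULT_DEFECT_TABLES.items()
    }

    return SyntheticStudy(
        config=config,
        templates=templates,
        parental_heads=parental_heads,
        measurements=measurements,
        wildtype_symmetry=wildtype_symmetry,
        hybrid_symmetry=hybrid_symmetry,
        appendages=appendages,
        cohorts=cohorts,
        truth=pd.DataFrame(truth_rows),
    )
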