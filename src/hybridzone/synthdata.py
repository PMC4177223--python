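"""Synthetic two-species hybrid-zone data generator.

Generates everything the analysis pipeline consumes: two parental
microsatellite populations with tunable differentiation, gametic crosses
(F1, F2, backcrosses) with faithful uniparental/sex-linked inheritance,
spatial coordinates arranged around a contact polyline, and two-cluster
morphometrics with sexual dimorphism in the larger species.  The same
machinery emulates the simulation step used for threshold calibration
(parental genotypes resampled from estimated frequencies, hybrid
categories produced by drawing gametes from simulated parents, pairing
parents with replacement).

Allele-frequency divergence between the two parental gene pools follows a
Balding–Nichols construction: both population frequency vectors are drawn
from a Dirichlet centred on a shared ancestral frequency vector with
concentration ``(1 - F)/F``, so a single parameter ``F`` ("divergence")
maps monotonically to the expected FST between the populations.  Repeat
sizes are spaced by 2 bp (dinucleotide convention) so that RST behaves
realistically.  Loci are unlinked and there is no mutation model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeTable, write_genepop
from .popgen import reynolds_fst

__all__ = [
    "LocusModel",
    "CrossCategory",
    "StudyConfig",
    "StudyData",
    "make_locus_models",
    "sample_parental",
    "cross",
    "build_study",
    "apply_dropout",
    "calibrate_divergence",
    "MEASUREMENTS",
]

CATEGORIES = ("PURE_A", "PURE_B", "F1", "F2", "BX_A", "BX_B")
HYBRID_CATEGORIES = ("F1", "F2", "BX_A", "BX_B")

# kept for interface symmetry with the enumeration used throughout
CrossCategory = str


@dataclass
class LocusModel:
    """Allele repeat sizes and parental frequency vectors at one locus."""

    locus_id: str
    alleles: list[int]
    freqs_a: np.ndarray
    freqs_b: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_a = np.asarray(self.freqs_a, dtype=float)
        self.freqs_b = np.asarray(self.freqs_b, dtype=float)
        if len(self.alleles) == 0:
            raise ValueError("allele list is empty")
        if any(b <= a for a, b in zip(self.alleles, self.alleles[1:])):
            raise ValueError("repeat sizes must be strictly increasing")
        for f in (self.freqs_a, self.freqs_b):
            if f.shape != (len(self.alleles),):
                raise ValueError("frequency vector length mismatch")
            if abs(f.sum() - 1.0) > 1e-9:
                raise ValueError("frequencies do not sum to 1")

    def freqs(self, pop: str) -> np.ndarray:
        if pop == "A":
            return self.freqs_a
        if pop == "B":
            return self.freqs_b
        raise ValueError(f"unknown population {pop!r}")


def make_locus_models(
    n_loci: int,
    n_alleles: int,
    divergence: float,
    seed: int = 0,
) -> list[LocusModel]:
    """Draw locus models whose expected FST grows with ``divergence``.

    ``divergence`` is the Balding–Nichols F parameter in (0, 1): the two
    population frequency vectors at each locus are independent draws from
    Dirichlet(ancestral * (1 - F)/F) around a shared ancestral vector.
    """
    if n_loci < 1 or n_alleles < 2:
        raise ValueError("need n_loci >= 1 and n_alleles >= 2")
    if not (0.0 < divergence < 1.0):
        raise ValueError("divergence must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    conc = (1.0 - divergence) / divergence
    models = []
    for l in range(n_loci):
        base = int(rng.integers(40, 61)) * 2  # even dinucleotide base size
        alleles = [base + 2 * k for k in range(n_alleles)]
        ancestral = rng.dirichlet(np.ones(n_alleles))
        fa = rng.dirichlet(np.maximum(ancestral * conc, 1e-9))
        fb = rng.dirichlet(np.maximum(ancestral * conc, 1e-9))
        models.append(LocusModel(f"L{l + 1:02d}", alleles, fa, fb))
    return models


# ----------------------------------------------------------------------
# parental sampling and gametic crosses
# ----------------------------------------------------------------------

def _draw_genotypes(models, pop: str, n: int, rng) -> np.ndarray:
    """(n, L, 2) allele-size draws under HWE, loci independent."""
    out = np.empty((n, len(models), 2), dtype=np.int32)
    for l, m in enumerate(models):
        sizes = np.asarray(m.alleles, dtype=np.int32)
        out[:, l, :] = rng.choice(sizes, size=(n, 2), p=m.freqs(pop))
    return out


def sample_parental(
    models: list[LocusModel],
    pop: str,
    n: int,
    seed: int = 0,
    id_prefix: str | None = None,
) -> GenotypeTable:
    """Sample ``n`` parental individuals of population 'A' or 'B' under HWE."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or f"P{pop}"
    return GenotypeTable(
        ids=[f"{prefix}{i + 1:04d}" for i in range(n)],
        loci=[m.locus_id for m in models],
        alleles=_draw_genotypes(models, pop, n, rng),
        population=np.full(n, pop, dtype=object),
        phenotype=np.full(n, pop, dtype=object),
    )


class _Parent:
    """A simulated parent: genotype plus sex-linked/uniparental origins."""

    __slots__ = ("genotype", "sex", "mt", "x", "y")

    def __init__(self, genotype, sex, mt, x, y):
        self.genotype = genotype  # (L, 2)
        self.sex = sex
        self.mt = mt
        self.x = x  # list of origin labels (1 for males, 2 for females)
        self.y = y  # origin label or None


def _make_pure(models, pop: str, sex: str, rng) -> _Parent:
    g = _draw_genotypes(models, pop, 1, rng)[0]
    if sex == "F":
        return _Parent(g, "F", pop, [pop, pop], None)
    return _Parent(g, "M", pop, [pop], pop)


def _other(pop: str) -> str:
    return "B" if pop == "A" else "A"


def _mate(dam: _Parent, sire: _Parent, sex: str, rng) -> _Parent:
    L = dam.genotype.shape[0]
    gam_d = dam.genotype[np.arange(L), rng.integers(0, 2, size=L)]
    gam_s = sire.genotype[np.arange(L), rng.integers(0, 2, size=L)]
    g = np.stack([gam_d, gam_s], axis=1)
    x_from_dam = dam.x[int(rng.integers(0, len(dam.x)))]
    if sex == "M":
        return _Parent(g, "M", dam.mt, [x_from_dam], sire.y)
    return _Parent(g, "F", dam.mt, [x_from_dam, sire.x[0]], None)


def _make_f1(models, dam_species: str, sex: str, rng) -> _Parent:
    dam = _make_pure(models, dam_species, "F", rng)
    sire = _make_pure(models, _other(dam_species), "M", rng)
    return _mate(dam, sire, sex, rng)


def cross(
    category: str,
    models: list[LocusModel],
    n: int,
    seed: int = 0,
    f1_dam_species: str = "B",
    bx_dam: str = "hybrid",
    id_prefix: str | None = None,
) -> tuple[GenotypeTable, pd.DataFrame]:
    """Simulate ``n`` offspring of one cross category.

    F1 pairs a pure-A and pure-B parent (dam species configurable, default
    B); F2 pairs two independently simulated F1s; backcrosses pair an F1
    with a pure parent of the named species (``bx_dam`` selects whether the
    hybrid or the parental individual is the dam).  Parents are drawn with
    replacement.  mtDNA follows the dam, Y the sire, X copies per sex.

    Returns the offspring genotype table and a haplotype-origin table
    (columns: individual_id, sex, mtdna, x1, x2, y; empty string = absent).
    The mating design is recorded in ``DataFrame.attrs``.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown cross category {category!r}")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    prefix = id_prefix or category
    ids, genos, hap_rows = [], [], []
    for i in range(n):
        sex = "M" if rng.random() < 0.5 else "F"
        if category in ("PURE_A", "PURE_B"):
            child = _make_pure(models, category[-1], sex, rng)
        elif category == "F1":
            child = _make_f1(models, f1_dam_species, sex, rng)
        elif category == "F2":
            dam = _make_f1(models, f1_dam_species, "F", rng)
            sire = _make_f1(models, f1_dam_species, "M", rng)
            child = _mate(dam, sire, sex, rng)
        else:  # backcross
            parental = category[-1]
            if bx_dam == "hybrid":
                dam = _make_f1(models, f1_dam_species, "F", rng)
                sire = _make_pure(models, parental, "M", rng)
            elif bx_dam == "parental":
                dam = _make_pure(models, parental, "F", rng)
                sire = _make_f1(models, f1_dam_species, "M", rng)
            else:
                raise ValueError("bx_dam must be 'hybrid' or 'parental'")
            child = _mate(dam, sire, sex, rng)
        ids.append(f"{prefix}{i + 1:04d}")
        genos.append(child.genotype)
        hap_rows.append(
            {
                "individual_id": ids[-1],
                "sex": child.sex,
                "mtdna": child.mt,
                "x1": child.x[0],
                "x2": child.x[1] if len(child.x) > 1 else "",
                "y": child.y or "",
            }
        )
    gt = GenotypeTable(
        ids=ids,
        loci=[m.locus_id for m in models],
        alleles=np.asarray(genos, dtype=np.int32),
        population=np.full(n, category, dtype=object),
    )
    haps = pd.DataFrame(hap_rows)
    haps.attrs["design"] = {
        "category": category,
        "f1_dam_species": f1_dam_species,
        "bx_dam": bx_dam,
    }
    return gt, haps


def apply_dropout(gt: GenotypeTable, rate: float, seed: int = 0) -> GenotypeTable:
    """Mask whole genotype calls at random with the given per-call rate."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("dropout rate must be in [0, 1)")
    if rate == 0.0:
        return gt
    rng = np.random.default_rng(seed)
    alleles = gt.alleles.copy()
    drop = rng.random((gt.n_individuals, gt.n_loci)) < rate
    alleles[drop] = MISSING
    return GenotypeTable(
        ids=list(gt.ids), loci=list(gt.loci), alleles=alleles,
        population=gt.population.copy(),
        phenotype=None if gt.phenotype is None else gt.phenotype.copy(),
    )


# ----------------------------------------------------------------------
# divergence calibration
# ----------------------------------------------------------------------

def calibrate_divergence(
    target_fst: float = 0.156,
    n_loci: int = 10,
    n_alleles: int = 8,
    n_replicates: int = 50,
    n_per_pop: int = 500,
    seed: int = 0,
    tol: float = 0.005,
    max_iter: int = 25,
) -> float:
    """Bisection on the drift parameter to hit a target mean Reynolds FST.

    Each evaluation averages the realized FST over ``n_replicates``
    independent locus sets, estimated on 2 x ``n_per_pop`` simulated
    individuals.  Replicate seeds are held fixed across evaluations
    (common random numbers) so the response is monotone in the parameter.
    """
    rep_seeds = np.random.SeedSequence(seed).generate_state(2 * n_replicates)

    def mean_fst(divergence: float) -> float:
        vals = []
        for r in range(n_replicates):
            models = make_locus_models(
                n_loci, n_alleles, divergence, seed=int(rep_seeds[2 * r]) % (2**31)
            )
            a = sample_parental(models, "A", n_per_pop, seed=int(rep_seeds[2 * r + 1]) % (2**31))
            b = sample_parental(models, "B", n_per_pop, seed=(int(rep_seeds[2 * r + 1]) + 1) % (2**31))
            vals.append(reynolds_fst(GenotypeTable.concat([a, b]), "A", "B"))
        return float(np.mean(vals))

    lo, hi = 0.005, 0.9
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = mean_fst(mid)
        if abs(f - target_fst) < tol:
            return mid
        if f < target_fst:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ----------------------------------------------------------------------
# full study builder
# ----------------------------------------------------------------------

MEASUREMENTS = [
    "body_length_cm", "tail_length_cm", "head_length_cm", "weight_kg",
    "shoulder_height_cm", "neck_circumference_cm", "breast_circumference_cm",
    "head_circumference_cm", "posterior_foot_length_cm", "fore_paw_length_cm",
    "fore_paw_width_cm", "hind_paw_length_cm", "hind_paw_width_cm",
    "fore_footpad_length_mm", "fore_footpad_width_mm", "hind_footpad_length_mm",
    "hind_footpad_width_mm", "fore_toe_length_mm", "fore_toe_width_mm",
    "hind_toe_length_mm", "upper_canine_width_mm", "lower_canine_width_mm",
    "upper_premolar_length_mm",
]

_BASELINE = np.array([
    78.0, 32.0, 13.5, 3.2, 26.0, 18.0, 30.0, 25.0, 14.5, 7.5, 5.0,
    8.0, 5.2, 28.0, 22.0, 26.0, 20.0, 18.0, 9.0, 17.0, 4.5, 4.0, 9.5,
])

DEFAULT_CONTACT_LINE = [(-57.5, -28.7), (-53.5, -30.0), (-49.8, -30.0)]


@dataclass
class StudyConfig:
    """Configuration of a full synthetic contact-zone study.

    The default sample mirrors a two-species contact-zone survey of 94
    individuals dominated by post-F1 hybrids: 30 pure A, 26 pure B, 2 F1,
    22 F2 and 7 backcrosses to each side.  Species A is the smaller
    Atlantic-Forest-side species (positive distances); species B is the
    larger Pampas-side species with male-biased sexual dimorphism.
    """

    counts: dict = field(default_factory=lambda: {
        "PURE_A": 30, "PURE_B": 26, "F1": 2, "F2": 22, "BX_A": 7, "BX_B": 7,
    })
    n_loci: int = 10
    n_alleles: int = 8
    divergence: float = 0.18
    contact_line: list = field(default_factory=lambda: list(DEFAULT_CONTACT_LINE))
    central_lon_range: tuple = (-54.0, -50.0)
    hybrid_spread_km: float = 30.0
    pure_offset_km: float = 120.0
    pure_spread_km: float = 45.0
    male_separation_sd: float = 4.0
    b_female_shift_sd: float = 0.8
    size_sensitivity: float = 0.06
    noise_cv: float = 0.02
    dropout: float = 0.0
    f1_dam_species: str = "B"
    bx_dam: str = "hybrid"

    def validate(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("category counts must be non-negative")
        unknown = set(self.counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in counts: {sorted(unknown)}")
        if not (0.0 < self.divergence < 1.0):
            raise ValueError("divergence must be in (0, 1)")
        if len(self.contact_line) < 2:
            raise ValueError("contact line needs at least 2 vertices")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class StudyData:
    """Bundle of all synthetic per-individual tables plus the locus truth."""

    genotypes: GenotypeTable
    haplotypes: pd.DataFrame
    coords: pd.DataFrame
    morpho: pd.DataFrame
    truth: pd.DataFrame
    models: list

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_genepop(self.genotypes, outdir / "genotypes.gen")
        self.haplotypes.to_csv(outdir / "haplotypes.csv", index=False)
        self.coords.to_csv(outdir / "coords.csv", index=False)
        self.morpho.to_csv(outdir / "morpho.csv", index=False)
        self.truth.to_csv(outdir / "truth.csv", index=False)


_KM_PER_DEG_LAT = 111.32


def _line_lat_at(lon: float, vertices: np.ndarray) -> float:
    """Latitude of the (west-to-east ordered) polyline at a longitude."""
    lons, lats = vertices[:, 0], vertices[:, 1]
    return float(np.interp(lon, lons, lats))


def build_study(config: StudyConfig | None = None, seed: int = 0) -> StudyData:
    """Generate the full study: genotypes, haplotypes, coordinates, morphology.

    Hybrid categories are placed around the contact polyline (perpendicular
    scatter ``hybrid_spread_km`` within the central longitude range) while
    pure individuals sit ``pure_offset_km`` away on their own species' side.
    Morphometric vectors are drawn from species-by-sex multivariate normals
    driven by one latent size factor; hybrids draw from the cluster of their
    assigned phenotype rather than an intermediate one, emulating the
    observation that admixed individuals need not be morphologically
    intermediate.  Truth labels are retained for recovery tests.
    """
    config = config or StudyConfig()
    config.validate()
    ss = np.random.SeedSequence(seed)
    s_models, s_cross, s_place, s_morph, s_drop = [
        int(x) % (2**31) for x in ss.generate_state(5)
    ]
    rng = np.random.default_rng(s_place)
    mrng = np.random.default_rng(s_morph)
    models = make_locus_models(config.n_loci, config.n_alleles,
                               config.divergence, seed=s_models)
    verts = np.asarray(config.contact_line, dtype=float)

    tables, hap_parts, truth_rows = [], [], []
    counter = 0
    for ci, cat in enumerate(CATEGORIES):
        n = int(config.counts.get(cat, 0))
        if n == 0:
            continue
        gt_c, haps_c = cross(
            cat, models, n, seed=s_cross + ci,
            f1_dam_species=config.f1_dam_species, bx_dam=config.bx_dam,
            id_prefix="tmp",
        )
        new_ids = [f"hz{counter + i + 1:04d}" for i in range(n)]
        counter += n
        gt_c = GenotypeTable(
            ids=new_ids, loci=gt_c.loci, alleles=gt_c.alleles,
            population=np.full(n, "RS", dtype=object),
        )
        haps_c = haps_c.assign(individual_id=new_ids)
        if cat in ("PURE_A", "PURE_B"):
            phen = [cat[-1]] * n
        else:
            # phenotype of a hybrid is its morphological cluster assignment
            phen = ["A" if rng.random() < 0.5 else "B" for _ in range(n)]
        for i, iid in enumerate(new_ids):
            truth_rows.append({
                "individual_id": iid, "category": cat,
                "phenotype": phen[i], "sex": haps_c["sex"].iloc[i],
            })
        tables.append(gt_c)
        hap_parts.append(haps_c)

    truth = pd.DataFrame(truth_rows)
    gt = GenotypeTable.concat(tables) if tables else GenotypeTable(
        ids=[], loci=[m.locus_id for m in models],
        alleles=np.empty((0, config.n_loci, 2), dtype=np.int32),
        population=np.empty(0, dtype=object),
    )
    if len(truth):
        gt.phenotype = truth["phenotype"].to_numpy(dtype=object)
    haplotypes = (
        pd.concat(hap_parts, ignore_index=True)
        if hap_parts
        else pd.DataFrame(columns=["individual_id", "sex", "mtdna", "x1", "x2", "y"])
    )

    # ---- placement around the contact line -------------------------------
    lon_lo, lon_hi = float(verts[0, 0]), float(verts[-1, 0])
    coords_rows = []
    for row in truth.itertuples():
        cat = row.category
        if cat in ("PURE_A", "PURE_B"):
            lon = rng.uniform(lon_lo, lon_hi)
            side = 1.0 if cat == "PURE_A" else -1.0
            d_km = side * rng.normal(config.pure_offset_km, config.pure_spread_km)
        else:
            lon = rng.uniform(*config.central_lon_range)
            d_km = rng.normal(0.0, config.hybrid_spread_km)
        lat = _line_lat_at(lon, verts) + d_km / _KM_PER_DEG_LAT
        coords_rows.append({
            "individual_id": row.individual_id, "lon": lon, "lat": lat,
        })
    coords = pd.DataFrame(coords_rows)

    # ---- morphometrics ---------------------------------------------------
    morph_rows = []
    for row in truth.itertuples():
        mu = 0.0
        if row.phenotype == "B":
            mu = (config.male_separation_sd if row.sex == "M"
                  else config.b_female_shift_sd)
        z = mrng.normal(mu, 1.0)
        vals = _BASELINE * (1.0 + config.size_sensitivity * z)
        vals = vals + mrng.normal(0.0, config.noise_cv * _BASELINE)
        vals = np.maximum(vals, 0.01)
        rec = {"individual_id": row.individual_id, "sex": row.sex}
        rec.update({m: round(float(v), 3) for m, v in zip(MEASUREMENTS, vals)})
        morph_rows.append(rec)
    morpho = pd.DataFrame(morph_rows)

    if config.dropout > 0:
        gt = apply_dropout(gt, config.dropout, seed=s_drop)
    return StudyData(gt, haplotypes, coords, morpho, truth, models)
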