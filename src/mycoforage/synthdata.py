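"""Synthetic cafeteria-study generator with known ground truth.

Emulates a mesh-bag "cafeteria" field experiment: replicate circles
(cafeterias) of six root-excluding ingrowth bags — four soil substrates and
two inert sand substrates — incubated around a central root sample, replicated
within forest sites.  The canonical geometry is 10 sites x 5 cafeterias x 6
substrates = 300 bags plus 50 root samples.

The forward model has three layers:

1. latent genus communities — site-level Dirichlet compositions, cafeteria
   root communities drawn around them, and bag communities obtained by
   tilting the root community with a per-genus bag enrichment factor and
   per-substrate preference multipliers;
2. sequencing counts — negative-binomial depths and Dirichlet-multinomial
   taxon counts, with pre-incubation "background" community DNA admixed into
   bag samples at a per-substrate fraction (soil substrates retain residual
   ectomycorrhizal DNA at roughly 0.6-5.6% of reads; sands are clean);
3. tagged amplicon reads — one read per count unit, with sample tags and
   primers attached, substitution errors, Phred qualities, and optionally
   planted "spoiled" reads whose defect type is recorded as truth.

Every routine is deterministic given its seed.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Substrate",
    "StudyDesign",
    "GenusProfile",
    "SequencingModel",
    "SOIL_CLASSES",
    "SAND_CLASSES",
    "default_substrates",
    "default_genus_profiles",
    "load_genus_traits",
    "generate_design",
    "simulate_latent_communities",
    "simulate_counts",
    "simulate_background_counts",
    "background_reference_table",
    "generate_reference_sequences",
    "make_tag_scheme",
    "simulate_reads",
    "FWD_PRIMER",
    "REV_PRIMER",
]

# fITS7 / ITS4, the primer pair bracketing the fungal ITS2 region.
FWD_PRIMER = "GTGARTCATCGAATCTTTG"
REV_PRIMER = "TCCTCCGCTTATTGATATGC"

SOIL_CLASSES = frozenset({"organic_soil", "mull_soil"})
SAND_CLASSES = frozenset({"sand", "sand_apatite"})

DNA = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Substrate:
    """One ingrowth-bag substrate.

    ``background_emf_fraction`` is the share of reads in the pre-incubated
    substrate that stem from residual ectomycorrhizal DNA (zero for sands).
    """

    substrate_id: str
    substrate_class: str
    background_emf_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.substrate_class not in SOIL_CLASSES | SAND_CLASSES:
            raise ValueError(f"unknown substrate class {self.substrate_class!r}")
        if not 0.0 <= self.background_emf_fraction <= 1.0:
            raise ValueError("background_emf_fraction must be in [0, 1]")

    @property
    def is_soil(self) -> bool:
        return self.substrate_class in SOIL_CLASSES


def default_substrates() -> list[Substrate]:
    """The six canonical substrates with their residual-EMF read shares.

    Four pre-incubated soils carry 0.6-5.6% residual ectomycorrhizal DNA;
    the two sand substrates are inert.
    """
    return [
        Substrate("organic_central", "organic_soil", 0.056),
        Substrate("mull_central", "mull_soil", 0.045),
        Substrate("organic_south", "organic_soil", 0.006),
        Substrate("organic_south_P", "organic_soil", 0.031),
        Substrate("sand", "sand", 0.0),
        Substrate("sand_apatite", "sand_apatite", 0.0),
    ]


@dataclass
class StudyDesign:
    """The enumerated sample list of one cafeteria experiment.

    ``samples`` has one row per potential sample with columns
    ``sample_id, site, cafeteria, sample_type, recovered`` where
    ``sample_type`` is a substrate id for bags and ``"root"`` for the central
    root sample; ``cafeteria`` ids are globally unique.  ``recovered`` encodes
    simulated field loss of bags (roots are always recovered).
    """

    samples: pd.DataFrame
    substrates: list[Substrate]
    seed: int

    @property
    def bags(self) -> pd.DataFrame:
        return self.samples[self.samples["sample_type"] != "root"]

    @property
    def roots(self) -> pd.DataFrame:
        return self.samples[self.samples["sample_type"] == "root"]

    @property
    def n_cafeterias(self) -> int:
        return self.samples["cafeteria"].nunique()

    @property
    def recovered(self) -> pd.DataFrame:
        return self.samples[self.samples["recovered"]]


def generate_design(
    n_sites: int = 10,
    cafeterias_per_site: int = 5,
    substrates: list[Substrate] | None = None,
    include_roots: bool = True,
    loss_probability: float = 23 / 300,
    seed: int = 0,
) -> StudyDesign:
    """Enumerate the sampling hierarchy and simulate bag recovery.

    Bag loss is independent Bernoulli per bag with ``loss_probability``
    (default matches the observed attrition of 23 of 300 bags).  Root samples
    are never lost.
    """
    if n_sites <= 0 or cafeterias_per_site <= 0:
        raise ValueError("site and cafeteria counts must be positive")
    if substrates is None:
        substrates = default_substrates()
    if not substrates:
        raise ValueError("substrate list must be non-empty")
    if not 0.0 <= loss_probability < 1.0:
        raise ValueError("loss_probability must be in [0, 1)")

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(1, n_sites + 1):
        site = f"S{s:02d}"
        for c in range(1, cafeterias_per_site + 1):
            caf = f"{site}C{c}"
            for sub in substrates:
                rows.append(
                    {
                        "sample_id": f"{caf}_{sub.substrate_id}",
                        "site": site,
                        "cafeteria": caf,
                        "sample_type": sub.substrate_id,
                        "recovered": True,
                    }
                )
            if include_roots:
                rows.append(
                    {
                        "sample_id": f"{caf}_root",
                        "site": site,
                        "cafeteria": caf,
                        "sample_type": "root",
                        "recovered": True,
                    }
                )
    samples = pd.DataFrame(rows)
    is_bag = samples["sample_type"] != "root"
    lost = rng.random(int(is_bag.sum())) < loss_probability
    samples.loc[is_bag, "recovered"] = ~lost
    return StudyDesign(samples=samples, substrates=list(substrates), seed=seed)


# ---------------------------------------------------------------------------
# genus profiles
# ---------------------------------------------------------------------------

@dataclass
class GenusProfile:
    """Latent ecology of one genus in the simulator.

    ``bag_enrichment`` is the true bag:root abundance tilt (the quantity the
    bags-vs-roots log ratio estimates) and ``substrate_preference`` the
    per-substrate multipliers (the quantity the soil-vs-sand log ratio
    estimates).  Both are multiplicative and renormalised within each bag, so
    only their ratios between genera are identified.
    """

    genus: str
    exploration_type: str = "unknown"
    root_affinity: float = 1.0
    bag_enrichment: float = 1.0
    substrate_preference: dict[str, float] = field(default_factory=dict)
    is_emf: bool = True

    def __post_init__(self) -> None:
        if self.root_affinity < 0:
            raise ValueError("root_affinity must be nonnegative")
        if self.bag_enrichment <= 0:
            raise ValueError("bag_enrichment must be positive")
        for sub, m in self.substrate_preference.items():
            if m < 0:
                raise ValueError(f"negative preference for {sub}")

    def preference(self, substrate_id: str) -> float:
        return self.substrate_preference.get(substrate_id, 1.0)


def load_genus_traits() -> pd.DataFrame:
    """Trait table (exploration type, hydrophobicity) of the 12 focal genera."""
    ref = importlib.resources.files("mycoforage.data") / "genus_traits.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def default_genus_profiles(seed: int = 0) -> list[GenusProfile]:
    """Profiles for the 12 focal ectomycorrhizal genera plus saprotrophs.

    Root affinities are drawn once (seeded) from a lognormal so communities
    are realistically uneven; three non-ectomycorrhizal genera absorb roughly
    60% of reads so that the ectomycorrhizal share of the total community
    falls in the 30-45% range typical of post-incubation samples.  Fringe-type
    genera get a soil preference and contact-type genera a low bag enrichment,
    mirroring the foraging contrasts the analysis is designed to detect.
    """
    traits = load_genus_traits()
    rng = np.random.default_rng(seed)
    soil_ids = ["organic_central", "mull_central", "organic_south", "organic_south_P"]
    profiles: list[GenusProfile] = []
    for _, row in traits.iterrows():
        et = row["exploration_type"]
        enrich, pref = 1.0, {}
        if et == "contact":
            enrich = 0.3
        elif et == "medium-distance fringe":
            enrich = 2.0
            pref = {s: 3.0 for s in soil_ids}
        elif et == "short-distance":
            enrich = 1.5
        profiles.append(
            GenusProfile(
                genus=row["genus"],
                exploration_type=et,
                root_affinity=float(rng.lognormal(0.0, 0.7)),
                bag_enrichment=enrich,
                substrate_preference=pref,
                is_emf=True,
            )
        )
    emf_total = sum(p.root_affinity for p in profiles)
    for name, share in [("Mortierella", 0.5), ("Penicillium", 0.3), ("Trichoderma", 0.2)]:
        profiles.append(
            GenusProfile(
                genus=name,
                exploration_type="none",
                # saprotrophs jointly ~60% of the community
                root_affinity=1.5 * emf_total * share,
                bag_enrichment=1.0,
                is_emf=False,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# latent communities
# ---------------------------------------------------------------------------

def simulate_latent_communities(
    design: StudyDesign,
    genera: list[GenusProfile],
    seed: int = 0,
    site_concentration: float = 30.0,
    cafeteria_concentration: float = 100.0,
) -> pd.DataFrame:
    """Draw latent relative abundances for every sample in the design.

    Site compositions are Dirichlet draws weighted by root affinity; each
    cafeteria's root community is a Dirichlet draw around its site
    composition.  Bag communities tilt the root community by
    ``bag_enrichment x substrate_preference[substrate]`` and renormalise;
    sequencing noise (including per-bag overdispersion) is added later by
    :func:`simulate_counts`.

    Returns a samples x genera DataFrame of proportions (rows sum to 1),
    indexed by sample_id, covering recovered and lost samples alike.
    """
    if not genera:
        raise ValueError("need at least one genus profile")
    if not any(g.is_emf for g in genera):
        raise ValueError("need at least one ectomycorrhizal genus")
    rng = np.random.default_rng(seed)
    names = [g.genus for g in genera]
    if len(set(names)) != len(names):
        raise ValueError("genus names must be unique")
    affinity = np.array([g.root_affinity for g in genera], dtype=float)
    if affinity.sum() <= 0:
        raise ValueError("total root affinity must be positive")
    enrich = np.array([g.bag_enrichment for g in genera], dtype=float)

    site_comp: dict[str, np.ndarray] = {}
    for site in design.samples["site"].unique():
        alpha = site_concentration * affinity / affinity.sum()
        site_comp[site] = rng.dirichlet(np.maximum(alpha, 1e-12))

    pref = {
        sub.substrate_id: np.array([g.preference(sub.substrate_id) for g in genera])
        for sub in design.substrates
    }

    rows, index = [], []
    for caf, group in design.samples.groupby("cafeteria", sort=False):
        site = group["site"].iloc[0]
        alpha = cafeteria_concentration * site_comp[site]
        root = rng.dirichlet(np.maximum(alpha, 1e-12))
        for _, sample in group.iterrows():
            if sample["sample_type"] == "root":
                rows.append(root)
            else:
                w = root * enrich * pref[sample["sample_type"]]
                total = w.sum()
                if total <= 0:
                    raise ValueError(
                        f"all-zero latent community in bag {sample['sample_id']}"
                    )
                rows.append(w / total)
            index.append(sample["sample_id"])
    return pd.DataFrame(rows, index=pd.Index(index, name="sample_id"), columns=names)


# ---------------------------------------------------------------------------
# sequencing counts
# ---------------------------------------------------------------------------

@dataclass
class SequencingModel:
    """Noise model for the sequencing layer.

    ``taxon_overdispersion`` is the Dirichlet concentration of the
    Dirichlet-multinomial count draw (larger = closer to multinomial;
    ``inf``/0-dispersion handled as pure multinomial).  ``depth_dispersion``
    is the negative-binomial dispersion of per-sample depth (0 = fixed
    depth).  ``error_rate`` and the quality parameters drive read simulation.
    """

    mean_depth: float = 10_000.0
    depth_dispersion: float = 0.1
    taxon_overdispersion: float = 200.0
    error_rate: float = 0.002
    mean_quality: float = 30.0
    min_quality: float = 10.0

    def __post_init__(self) -> None:
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.depth_dispersion < 0 or self.taxon_overdispersion < 0:
            raise ValueError("dispersions must be nonnegative")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


def _draw_depth(model: SequencingModel, rng: np.random.Generator) -> int:
    if model.depth_dispersion == 0:
        return max(1, int(round(model.mean_depth)))
    # NB with mean m and variance m + disp * m^2
    k = 1.0 / model.depth_dispersion
    p = k / (k + model.mean_depth)
    return max(1, int(rng.negative_binomial(k, p)))


def _draw_counts(
    p: np.ndarray, depth: int, model: SequencingModel, rng: np.random.Generator
) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    p = p / p.sum()
    if np.isfinite(model.taxon_overdispersion) and model.taxon_overdispersion > 0:
        alpha = model.taxon_overdispersion * p
        pos = alpha > 0
        q = np.zeros_like(p)
        q[pos] = rng.dirichlet(alpha[pos])
        p = q
    return rng.multinomial(depth, p)


def background_profiles(
    substrates: list[Substrate],
    genera: list[GenusProfile],
    n_background_taxa: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-substrate composition of pre-incubation (background) DNA.

    Each soil substrate's background is the substrate's residual
    ectomycorrhizal DNA — spread over the ``n_background_taxa`` highest-
    affinity ectomycorrhizal genera with seeded random weights — at
    ``background_emf_fraction`` of reads, topped up with non-ectomycorrhizal
    taxa.  Rows (substrates) sum to 1; sands are entirely non-EMF.
    """
    rng = np.random.default_rng(seed)
    names = [g.genus for g in genera]
    emf = sorted(
        (g for g in genera if g.is_emf), key=lambda g: -g.root_affinity
    )[:n_background_taxa]
    non_emf = [g for g in genera if not g.is_emf]
    if not non_emf:
        raise ValueError("background profile needs at least one non-EMF genus")
    rows = []
    for sub in substrates:
        prof = pd.Series(0.0, index=names)
        f = sub.background_emf_fraction
        if f > 0:
            w = rng.dirichlet(np.full(len(emf), 2.0))
            for g, wi in zip(emf, w):
                prof[g.genus] = f * wi
        w = rng.dirichlet(np.full(len(non_emf), 2.0))
        for g, wi in zip(non_emf, w):
            prof[g.genus] = (1.0 - f) * wi
        rows.append(prof.rename(sub.substrate_id))
    out = pd.DataFrame(rows)
    out.index.name = "substrate"
    return out


def simulate_counts(
    latent: pd.DataFrame,
    design: StudyDesign,
    model: SequencingModel,
    seed: int = 0,
    background_emf: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Draw sequencing counts for every recovered sample.

    Per sample: depth ~ negative binomial, taxon counts ~ Dirichlet-
    multinomial around the latent proportions.  ``background_emf`` is a
    substrates x taxa table of pre-incubation ectomycorrhizal relative
    abundances (each row summing to that substrate's
    ``background_emf_fraction``); bag proportions become
    ``(1 - f) * latent + background_emf_row`` so that the residual DNA
    appears in the post-incubation sample at exactly its pre-incubation
    relative abundance — the assumption the downstream subtraction makes.
    Roots get no background.  Rows of the result sum to the drawn depths.
    """
    bad = np.abs(latent.sum(axis=1) - 1.0) > 1e-9
    if bad.any():
        raise ValueError("latent rows must sum to 1")
    rng = np.random.default_rng(seed)
    rows, index = [], []
    meta = design.recovered.set_index("sample_id")
    for sample_id, m in meta.iterrows():
        if sample_id not in latent.index:
            raise KeyError(f"sample {sample_id} missing from latent table")
        p = latent.loc[sample_id].to_numpy(dtype=float)
        stype = m["sample_type"]
        if stype != "root" and background_emf is not None:
            bg = background_emf.loc[stype].reindex(latent.columns).fillna(0.0)
            f = float(bg.sum())
            if f > 0:
                p = (1.0 - f) * p + bg.to_numpy(dtype=float)
        depth = _draw_depth(model, rng)
        rows.append(_draw_counts(p, depth, model, rng))
        index.append(sample_id)
    return pd.DataFrame(
        np.array(rows, dtype=np.int64),
        index=pd.Index(index, name="sample_id"),
        columns=latent.columns,
    )


def simulate_background_counts(
    substrates: list[Substrate],
    background: pd.DataFrame,
    model: SequencingModel,
    n_replicates: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sequence the pre-incubation substrates themselves.

    Returns (counts, metadata): one row per substrate replicate, drawn from
    the substrate's background profile — the tables an analyst would use to
    estimate the background correction.  The realized ectomycorrhizal read
    share equals the substrate's ``background_emf_fraction`` up to sampling
    error.
    """
    rng = np.random.default_rng(seed)
    rows, ids, meta = [], [], []
    for sub in substrates:
        p = background.loc[sub.substrate_id].to_numpy(dtype=float)
        for r in range(n_replicates):
            depth = _draw_depth(model, rng)
            rows.append(_draw_counts(p, depth, model, rng))
            ids.append(f"bg_{sub.substrate_id}_{r + 1}")
            meta.append(
                {
                    "sample_id": f"bg_{sub.substrate_id}_{r + 1}",
                    "site": "none",
                    "cafeteria": "none",
                    "sample_type": sub.substrate_id,
                }
            )
    counts = pd.DataFrame(
        np.array(rows, dtype=np.int64),
        index=pd.Index(ids, name="sample_id"),
        columns=background.columns,
    )
    return counts, pd.DataFrame(meta).set_index("sample_id")


def background_reference_table(
    substrates: list[Substrate],
    background: pd.DataFrame,
    emf_taxa: list[str],
) -> pd.DataFrame:
    """Exact pre-incubation EMF relative abundances per substrate.

    The noise-free version of what :func:`simulate_background_counts` lets an
    analyst estimate: rows are substrates, columns the ectomycorrhizal taxa,
    values their relative abundance in the total pre-incubation community
    (each row sums to the substrate's ``background_emf_fraction``).  This is
    both what :func:`simulate_counts` admixes into bags and what the
    downstream correction subtracts.
    """
    cols = [t for t in emf_taxa if t in background.columns]
    out = background.reindex([s.substrate_id for s in substrates])[cols].copy()
    out.index.name = "substrate"
    return out


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(DNA[rng.integers(0, 4, size=length)])


def generate_reference_sequences(
    taxa: list[str],
    length: int = 250,
    min_divergence: float = 0.05,
    seed: int = 0,
    max_tries: int = 200,
) -> dict[str, str]:
    """Random amplicon references with all pairwise identities below
    ``1 - min_divergence`` (ungapped proxy: Hamming distance at equal length).
    """
    rng = np.random.default_rng(seed)
    refs: dict[str, str] = {}
    arrs: list[np.ndarray] = []
    for taxon in taxa:
        for _ in range(max_tries):
            cand = rng.integers(0, 4, size=length)
            if all(np.mean(cand != a) >= min_divergence for a in arrs):
                arrs.append(cand)
                refs[taxon] = "".join(DNA[cand])
                break
        else:
            raise RuntimeError("could not place divergent reference sequence")
    return refs


def make_tag_scheme(sample_ids: list[str], tag_length: int = 8, seed: int = 0) -> pd.DataFrame:
    """Unique forward/reverse tag pair per sample (columns: sample_id, fwd_tag,
    rev_tag)."""
    rng = np.random.default_rng(seed)
    seen: set[tuple[str, str]] = set()
    tags: set[str] = set()
    rows = []
    for sid in sample_ids:
        while True:
            f, r = _random_dna(rng, tag_length), _random_dna(rng, tag_length)
            if (f, r) not in seen and f not in tags and r not in tags:
                seen.add((f, r))
                tags.update((f, r))
                break
        rows.append({"sample_id": sid, "fwd_tag": f, "rev_tag": r})
    return pd.DataFrame(rows)


SPOILAGE_TYPES = ("short", "low_mean_quality", "low_base_quality", "bad_primer", "bad_tag")


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    quality: np.ndarray  # Phred scores, one per base
    true_sample: str
    true_taxon: str
    spoilage: str | None = None  # None = clean


def _phred_string(q: np.ndarray) -> str:
    return "".join(chr(int(x) + 33) for x in q)


def _other_base(b: str) -> str:
    """A concrete base guaranteed to differ from ``b`` (ambiguity codes too)."""
    return "A" if b in ("C", "G", "T") else "C"


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        subs = DNA[rng.integers(0, 4, size=int(hit.sum()))]
        arr[hit] = subs  # may resample the same base: effective rate 3/4 * rate
    return "".join(arr)


def simulate_reads(
    counts: pd.DataFrame,
    references: dict[str, str],
    tag_map: pd.DataFrame,
    model: SequencingModel,
    seed: int = 0,
    spoilage_fraction: float = 0.0,
    max_reads_per_sample: int | None = None,
) -> list[SimulatedRead]:
    """Turn a count table into tagged amplicon reads.

    Read layout: ``fwd_tag + fwd_primer + template + revcomp(rev_primer) +
    revcomp(rev_tag)``.  One read per count unit (optionally subsampled per
    sample); substitution errors at ``model.error_rate``; qualities drawn
    around ``model.mean_quality``.  A ``spoilage_fraction`` of reads is
    damaged in one of five ways (truncated template, low mean quality, one
    very-low-quality base, broken primer, broken tag) and labelled with its
    defect, giving downstream filters a planted ground truth.
    """
    for taxon in counts.columns:
        if taxon not in references:
            raise KeyError(f"no reference sequence for taxon {taxon!r}")
        if len(references[taxon]) < 120:
            raise ValueError(f"reference for {taxon!r} shorter than 120 bp")
    tags = tag_map.set_index("sample_id")
    rng = np.random.default_rng(seed)
    reads: list[SimulatedRead] = []
    n = 0
    for sample_id, row in counts.iterrows():
        if sample_id not in tags.index:
            raise KeyError(f"sample {sample_id} missing from tag map")
        fwd_tag = tags.loc[sample_id, "fwd_tag"]
        rev_tag = tags.loc[sample_id, "rev_tag"]
        units = np.repeat(counts.columns.to_numpy(), row.to_numpy())
        if max_reads_per_sample is not None and len(units) > max_reads_per_sample:
            units = rng.choice(units, size=max_reads_per_sample, replace=False)
        for taxon in units:
            n += 1
            template = _mutate(references[taxon], model.error_rate, rng)
            spoil = None
            fwd_tag_used, primer = fwd_tag, FWD_PRIMER
            qual_mean = model.mean_quality
            low_base_at = None
            if spoilage_fraction > 0 and rng.random() < spoilage_fraction:
                spoil = SPOILAGE_TYPES[rng.integers(0, len(SPOILAGE_TYPES))]
                if spoil == "short":
                    template = template[:90]
                elif spoil == "low_mean_quality":
                    qual_mean = 10.0
                elif spoil == "low_base_quality":
                    low_base_at = int(rng.integers(0, len(template)))
                elif spoil == "bad_primer":
                    # scramble 25% of primer positions: identity falls below 0.90
                    arr = np.array(list(primer))
                    k = max(3, len(arr) // 4)
                    pos = rng.choice(len(arr), size=k, replace=False)
                    arr[pos] = [_other_base(b) for b in arr[pos]]
                    primer = "".join(arr)
                elif spoil == "bad_tag":
                    arr = np.array(list(fwd_tag))
                    arr[0] = _other_base(arr[0])
                    fwd_tag_used = "".join(arr)
            seq = fwd_tag_used + primer + template + _revcomp(REV_PRIMER) + _revcomp(rev_tag)
            q = np.clip(
                rng.normal(qual_mean, 3.0, size=len(seq)).round(),
                model.min_quality if spoil != "low_mean_quality" else 2,
                41,
            ).astype(int)
            if low_base_at is not None:
                q[len(fwd_tag_used) + len(primer) + low_base_at] = 2
            reads.append(
                SimulatedRead(
                    read_id=f"read{n:07d}|{sample_id}|{taxon}"
                    + (f"|spoil={spoil}" if spoil else ""),
                    sequence=seq,
                    quality=q,
                    true_sample=str(sample_id),
                    true_taxon=str(taxon),
                    spoilage=spoil,
                )
            )
    return reads


def write_fastq(reads: list[SimulatedRead], path) -> None:
    """Write simulated reads as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{_phred_string(r.quality)}\n")


def write_reference_fasta(references: dict[str, str], genus_of: dict[str, str],
                          emf: dict[str, bool], path) -> None:
    """Write references with ``>taxon|genus|EMF-or-other`` headers."""
    with open(path, "w") as fh:
        for taxon, seq in references.items():
            guild = "EMF" if emf.get(taxon, False) else "other"
            fh.write(f">{taxon}|{genus_of.get(taxon, taxon)}|{guild}\n{seq}\n")


def write_tag_map(tag_map: pd.DataFrame, path) -> None:
    """Two-column TSV: sample_id, fwd_tag:rev_tag."""
    out = pd.DataFrame(
        {
            "sample_id": tag_map["sample_id"],
            "tags": tag_map["fwd_tag"] + ":" + tag_map["rev_tag"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
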