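"""Synthetic study generator with known ground truth.

Emulates the field data the pipeline consumes: COI-COII sequences built
from a tRNA-leu flank, an optional P-type element, one to three Q copies
and a COII flank, with point mutations and rare short indels; haplodiploid
worker genotypes at 13 microsatellite loci, including planted super-sister
pairs (same queen, same drone father, expected r = 0.75); and sampling
sites along two meridional transects with a logistic latitudinal cline in
lineage membership.

Design points worth knowing before using the defaults:

* Structure counts are apportioned deterministically (largest remainder)
  from the mixture weights, so ``n_samples=427`` with the default weights
  yields exactly the canonical counts {Q: 376, PQ: 1, PQQ: 36, PQQQ: 7,
  P0Q: 2, P0QQ: 5}.
* Independent samples sit at sites with a 7 km minimum separation
  (distinct apiaries are independent data points); each planted kin
  duplicate is placed 0.5-2 km from its focal sample and carries its
  focal's exact mtDNA sequence, so only planted pairs ever fall inside
  the 5 km deduplication radius.
* All randomness flows from one seed; identical seeds give byte-identical
  output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import GenotypeTable, MtSequence, write_fasta, write_genotypes
from .repeat_typing import ElementLibrary, default_library

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_sequences",
    "simulate_pedigree_genotypes",
    "simulate_geography",
    "simulate",
    "write_simulation",
]

#: canonical structure counts observed in a 427-bee survey, used as weights
DEFAULT_STRUCTURE_COUNTS = {
    "Q": 376,
    "PQ": 1,
    "PQQ": 36,
    "PQQQ": 7,
    "P0Q": 2,
    "P0QQ": 5,
}

STRUCTURE_LINEAGE = {
    "Q": "C",
    "PQ": "M",
    "PQQ": "M",
    "PQQQ": "M",
    "P0Q": "A",
    "P0QQ": "A",
}

#: per-lineage logistic cline coefficients (intercept, per-degree latitude
#: slope, west-vs-east transect contrast)
DEFAULT_CLINES = {
    "C": (21.578, -0.383, 0.340),
    "A": (-2.441, -0.044, 0.962),
    "M": (-29.638, 0.535, -0.615),
}


@dataclass
class SimConfig:
    """Study conditions for the generator (defaults mirror the survey)."""

    seed: int = 0
    n_samples: int = 444
    n_kin_pairs: int = 17
    structure_weights: dict = dc_field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE_COUNTS)
    )
    substitution_rate: float = 1.5e-4  # per site per individual
    indel_rate: float = 1e-5          # per site; lengths 1-3
    n_loci: int = 13
    n_alleles: int = 10
    #: transect meridians (deg E), latitude range (deg N) spanning ~900 km
    lon_west: float = 17.5
    lon_east: float = 23.0
    lat_range: tuple = (46.5, 54.5)
    lon_jitter: float = 0.5
    min_site_spacing_km: float = 7.0
    kin_distance_km: tuple = (0.5, 2.0)
    cline_lineage: str = "M"
    cline_coefficients: tuple = DEFAULT_CLINES["M"]

    def __post_init__(self):
        if not self.structure_weights:
            raise ValueError("structure_weights must be non-empty")
        if any(w < 0 for w in self.structure_weights.values()):
            raise ValueError("structure weights must be non-negative")
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError("rates must lie in [0, 1)")
        if self.n_kin_pairs * 2 > self.n_samples:
            raise ValueError("too many kin pairs for n_samples")


@dataclass
class GroundTruth:
    """Per-sample truth emitted alongside the synthetic files."""

    table: pd.DataFrame  # sample_id, structure, lineage, haplotype, role, kin_partner
    kin_pairs: list      # [(focal_id, duplicate_id), ...]

    def structure_counts(self) -> dict:
        return self.table["structure"].value_counts().to_dict()


def _apportion(weights: dict, n: int) -> dict:
    """Largest-remainder apportionment of n among weighted categories."""
    total = sum(weights.values())
    quotas = {k: n * w / total for k, w in weights.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_rem = sorted(
        weights, key=lambda k: (-(quotas[k] - counts[k]), k)
    )
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def _structure_sequence(structure: str, lib: ElementLibrary) -> str:
    parts = [lib.flanks["TRNA_LEU"]]
    i = 0
    while i < len(structure):
        name = "P0" if structure.startswith("P0", i) else structure[i]
        parts.append(lib.elements[name])
        i += len(name)
    parts.append(lib.flanks["COII"])
    return "".join(parts)


def _mutate(seq: str, cfg: SimConfig, rng: np.random.Generator) -> str:
    s = list(seq)
    n_sub = rng.binomial(len(s), cfg.substitution_rate)
    for i in rng.choice(len(s), size=n_sub, replace=False):
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    n_indel = rng.binomial(len(s), cfg.indel_rate)
    for _ in range(n_indel):
        pos = int(rng.integers(0, len(s)))
        length = int(rng.integers(1, 4))
        if rng.random() < 0.5 and len(s) > length:
            del s[pos:pos + length]
        else:
            s[pos:pos] = rng.choice(list("ACGT"), size=length).tolist()
    return "".join(s)


def _sample_sites(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Site coordinates with minimum spacing, via sequential rejection."""
    from .io_formats import haversine_km

    lat_lo, lat_hi = cfg.lat_range
    sites = []
    attempts = 0
    while len(sites) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("could not place sites at requested spacing")
        meridian = cfg.lon_west if rng.random() < 0.5 else cfg.lon_east
        lat = rng.uniform(lat_lo, lat_hi)
        lon = meridian + rng.uniform(-cfg.lon_jitter, cfg.lon_jitter)
        ok = all(
            haversine_km(lat, lon, la, lo) >= cfg.min_site_spacing_km
            for la, lo in sites
        )
        if ok:
            sites.append((lat, lon))
    return np.asarray(sites)


def simulate_geography(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    n: Optional[int] = None,
) -> pd.DataFrame:
    """Sites on two transects with i.i.d. logistic lineage presence.

    Presence of ``cfg.cline_lineage`` is Bernoulli with
    logit p = b0 + b_lat * latitude + b_west * 1[west of 20 E].
    Returns sample_id, latitude, longitude, transect, presence.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = n or cfg.n_samples
    sites = _sample_sites(cfg, n, rng)
    b0, b_lat, b_west = cfg.cline_coefficients
    west = (sites[:, 1] < 20.0).astype(float)
    eta = b0 + b_lat * sites[:, 0] + b_west * west
    p = 1.0 / (1.0 + np.exp(-eta))
    presence = (rng.random(n) < p).astype(int)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i + 1:04d}" for i in range(n)],
            "latitude": sites[:, 0],
            "longitude": sites[:, 1],
            "transect": np.where(west == 1.0, "west", "east"),
            "presence": presence,
        }
    )


def _assign_structures_with_cline(
    cfg: SimConfig, sites: np.ndarray, rng: np.random.Generator
) -> list[str]:
    """Assign exact structure counts to sites, cline-weighted by lineage.

    A- and M-lineage quotas are placed by Gumbel-top-k weighted sampling
    without replacement with weights from the per-lineage logistic clines,
    so counts stay exact while spatial trends match the generating model.
    """
    n = len(sites)
    counts = _apportion(cfg.structure_weights, n)
    lineage_counts: dict = {}
    for s, k in counts.items():
        lineage_counts[STRUCTURE_LINEAGE[s]] = lineage_counts.get(
            STRUCTURE_LINEAGE[s], 0
        ) + k

    west = (sites[:, 1] < 20.0).astype(float)
    assigned = np.full(n, "", dtype=object)
    remaining = np.arange(n)
    for lineage in ("M", "A"):  # C takes the rest
        k = lineage_counts.get(lineage, 0)
        if k == 0:
            continue
        b0, b_lat, b_west = DEFAULT_CLINES[lineage]
        eta = b0 + b_lat * sites[remaining, 0] + b_west * west[remaining]
        # Gumbel-top-k = weighted sampling without replacement
        keys = eta + rng.gumbel(size=len(remaining))
        take = remaining[np.argsort(-keys)[:k]]
        structures = [
            s for s, c in sorted(counts.items()) if STRUCTURE_LINEAGE[s] == lineage
            for _ in range(c)
        ]
        order = rng.permutation(k)
        for idx, si in zip(take, order):
            assigned[idx] = structures[si]
        remaining = np.asarray([i for i in remaining if i not in set(take.tolist())])
    c_structures = [
        s for s, c in sorted(counts.items()) if STRUCTURE_LINEAGE[s] == "C"
        for _ in range(c)
    ]
    order = rng.permutation(len(remaining))
    for idx, si in zip(remaining, order):
        assigned[idx] = c_structures[si]
    return assigned.tolist()


def simulate_sequences(
    cfg: SimConfig,
    lib: Optional[ElementLibrary] = None,
    rng: Optional[np.random.Generator] = None,
    structures: Optional[list] = None,
    sample_ids: Optional[list] = None,
) -> tuple[list[MtSequence], pd.DataFrame]:
    """COI-COII sequences for independent samples, with truth table.

    Structures default to an exact largest-remainder apportionment of
    ``cfg.structure_weights`` over ``cfg.n_samples - cfg.n_kin_pairs``
    independent samples.  Each sequence is flank + elements + flank with
    i.i.d. substitutions and rare indels.
    """
    lib = lib or default_library()
    rng = rng or np.random.default_rng(cfg.seed)
    n_ind = cfg.n_samples - cfg.n_kin_pairs
    if structures is None:
        counts = _apportion(cfg.structure_weights, n_ind)
        structures = [s for s, k in sorted(counts.items()) for _ in range(k)]
        structures = [structures[i] for i in rng.permutation(n_ind)]
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(len(structures))]
    seqs, rows = [], []
    for sid, structure in zip(sample_ids, structures):
        raw = _mutate(_structure_sequence(structure, lib), cfg, rng)
        seqs.append(MtSequence(sid, raw))
        rows.append(
            {
                "sample_id": sid,
                "structure": structure,
                "lineage": STRUCTURE_LINEAGE[structure],
                "role": "independent",
                "kin_partner": "",
            }
        )
    return seqs, pd.DataFrame(rows)


def simulate_pedigree_genotypes(
    cfg: SimConfig,
    sample_ids: list,
    kin_pairs: list,
    rng: Optional[np.random.Generator] = None,
) -> GenotypeTable:
    """Microsatellite genotypes: unrelated females plus super-sister pairs.

    Unrelated workers draw two alleles per locus from equifrequent allele
    pools.  For each planted pair, both members are daughters of one
    diploid queen and a single haploid drone: they share the drone allele
    at every locus and the same maternal allele with probability 1/2.
    """
    if cfg.n_loci < 2:
        raise ValueError("need at least 2 loci")
    rng = rng or np.random.default_rng(cfg.seed)
    loci = [f"L{j + 1:02d}" for j in range(cfg.n_loci)]
    alleles = {
        sid: {
            loc: tuple(sorted(rng.integers(100, 100 + cfg.n_alleles, 2).tolist()))
            for loc in loci
        }
        for sid in sample_ids
    }
    for focal, dup in kin_pairs:
        for loc in loci:
            queen = rng.integers(100, 100 + cfg.n_alleles, 2)
            drone = int(rng.integers(100, 100 + cfg.n_alleles))
            g_focal = (int(queen[rng.integers(0, 2)]), drone)
            g_dup = (int(queen[rng.integers(0, 2)]), drone)
            alleles[focal][loc] = tuple(sorted(g_focal))
            alleles[dup][loc] = tuple(sorted(g_dup))
    return GenotypeTable(list(sample_ids), loci, alleles)


def _offset_point(lat, lon, dist_km, bearing_rad):
    # small-displacement equirectangular offset; fine at km scales
    dlat = dist_km / 111.32 * np.cos(bearing_rad)
    dlon = dist_km / (111.32 * np.cos(np.radians(lat))) * np.sin(bearing_rad)
    return lat + dlat, lon + dlon


def simulate(
    cfg: SimConfig,
    lib: Optional[ElementLibrary] = None,
) -> tuple[list[MtSequence], GenotypeTable, pd.DataFrame, GroundTruth]:
    """Full synthetic study: sequences, genotypes, metadata and truth.

    ``cfg.n_samples`` total bees = ``n_samples - n_kin_pairs`` independent
    samples (exact structure apportionment, cline-weighted placement) plus
    one super-sister duplicate per planted kin pair, sharing its focal's
    exact mtDNA sequence and site (0.5-3 km away).
    """
    lib = lib or default_library()
    rng = np.random.default_rng(cfg.seed)
    n_ind = cfg.n_samples - cfg.n_kin_pairs

    sites = _sample_sites(cfg, n_ind, rng)
    structures = _assign_structures_with_cline(cfg, sites, rng)
    ids = [f"S{i + 1:04d}" for i in range(n_ind)]
    seqs, truth = simulate_sequences(
        cfg, lib, rng, structures=structures, sample_ids=ids
    )
    for s, (lat, lon) in zip(seqs, sites):
        s.latitude = float(lat)
        s.longitude = float(lon)

    focal_idx = rng.choice(n_ind, size=cfg.n_kin_pairs, replace=False)
    kin_pairs = []
    extra_rows = []
    for j, fi in enumerate(sorted(focal_idx.tolist())):
        focal = seqs[fi]
        dup_id = f"K{j + 1:03d}"
        d = rng.uniform(*cfg.kin_distance_km)
        bearing = rng.uniform(0, 2 * np.pi)
        lat, lon = _offset_point(focal.latitude, focal.longitude, d, bearing)
        dup = MtSequence(dup_id, focal.seq, float(lat), float(lon))
        seqs.append(dup)
        kin_pairs.append((focal.sample_id, dup_id))
        extra_rows.append(
            {
                "sample_id": dup_id,
                "structure": truth.loc[fi, "structure"],
                "lineage": truth.loc[fi, "lineage"],
                "role": "kin_duplicate",
                "kin_partner": focal.sample_id,
            }
        )
    truth = pd.concat([truth, pd.DataFrame(extra_rows)], ignore_index=True)
    truth.loc[truth["sample_id"].isin([f for f, _ in kin_pairs]), "kin_partner"] = [
        d for _, d in kin_pairs
    ]

    all_ids = [s.sample_id for s in seqs]
    gt = simulate_pedigree_genotypes(cfg, all_ids, kin_pairs, rng)

    meta = pd.DataFrame(
        {
            "sample_id": all_ids,
            "latitude": [s.latitude for s in seqs],
            "longitude": [s.longitude for s in seqs],
            "transect": ["west" if s.longitude < 20.0 else "east" for s in seqs],
        }
    )
    return seqs, gt, meta, GroundTruth(table=truth, kin_pairs=kin_pairs)


def write_simulation(out_dir, cfg: SimConfig, lib=None) -> dict:
    """Run :func:`simulate` and write seqs.fasta/genotypes.tsv/meta.tsv/truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seqs, gt, meta, truth = simulate(cfg, lib)
    paths = {
        "fasta": out / "seqs.fasta",
        "genotypes": out / "genotypes.tsv",
        "meta": out / "meta.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(seqs, paths["fasta"])
    write_genotypes(gt, paths["genotypes"])
    meta.to_csv(paths["meta"], sep="\t", index=False)
    truth.table.to_csv(paths["truth"], sep="\t", index=False)
    return paths
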