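"""Genotype, locality and contact-zone I/O.

Diploid multiallelic genotypes (microsatellite-style integer allele codes)
are held in :class:`GenotypeMatrix` and exchanged either as STRUCTURE-style
two-row text files or as long-format delimited tables.  Localities are plain
tables of decimal-degree coordinates (WGS84 assumed); transect positions are
great-circle distances from a designated origin locality.

The packaged contact-zone table summarises ten secondary contacts between
Western-Palearctic tree frog species: the species pair, its divergence time
(Ma), the putative epoch of first contact, and an ordered transition
category (``no_gene_flow < steep < wide``) reflecting the amount of
admixture observed at the contact.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing allele call inside a GenotypeMatrix
MISSING = -1
#: missing code used by STRUCTURE-format files on disk
STRUCTURE_MISSING = -9

#: mean Earth radius in km (IUGG), used for great-circle distances
EARTH_RADIUS_KM = 6371.0088

CONTACT_EPOCHS = ("Antiquity", ">=LGM", "post-glacial", "1950s")
TRANSITION_CATEGORIES = ("no_gene_flow", "steep", "wide")  # ordered: admixture amount


class GenotypeParseError(ValueError):
    """Raised when a genotype file is malformed (names the offending record)."""


@dataclass
class GenotypeMatrix:
    """Diploid multiallelic genotypes for individuals x loci.

    Parameters
    ----------
    ids : list of str
        Individual identifiers.
    pops : list of str
        Population label per individual (non-empty).
    loci : list of str
        Locus names.
    calls : ndarray of int, shape (n_individuals, n_loci, 2)
        Integer allele codes; :data:`MISSING` (-1) marks a missing slot.
    """

    ids: list[str]
    pops: list[str]
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, L = len(self.ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n} individuals x {L} loci x 2 allele slots"
            )
        if len(self.pops) != n:
            raise ValueError("one population label required per individual")
        if any(not p for p in self.pops):
            raise ValueError("population labels must be non-empty")
        valid = (self.calls >= 0) | (self.calls == MISSING)
        if not valid.all():
            raise ValueError("allele codes must be non-negative or the missing sentinel")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, mask: np.ndarray) -> "GenotypeMatrix":
        """Row-subset by boolean mask or index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypeMatrix(
            ids=[self.ids[i] for i in idx],
            pops=[self.pops[i] for i in idx],
            loci=list(self.loci),
            calls=self.calls[idx],
        )

    def by_population(self, pop: str) -> "GenotypeMatrix":
        return self.subset(np.array([p == pop for p in self.pops]))

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for p in self.pops:
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    def allele_count(self, locus_index: int) -> int:
        """Number of distinct observed alleles at a locus (codes assumed dense)."""
        obs = self.calls[:, locus_index, :]
        obs = obs[obs != MISSING]
        return int(obs.max()) + 1 if obs.size else 0

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.pops == other.pops
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class Locality:
    """One sampling locality (decimal degrees, WGS84)."""

    locality_id: str
    latitude: float
    longitude: float
    n: int = 0
    on_transect: bool = True

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} out of range for {self.locality_id}")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} out of range for {self.locality_id}")


@dataclass
class LocalityTable:
    """Collection of localities with unique ids."""

    localities: list[Locality] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [loc.locality_id for loc in self.localities]
        if len(set(ids)) != len(ids):
            raise ValueError("locality ids must be unique")

    def __iter__(self):
        return iter(self.localities)

    def __len__(self) -> int:
        return len(self.localities)

    def transect(self) -> list[Locality]:
        return [loc for loc in self.localities if loc.on_transect]


@dataclass(frozen=True)
class ContactZoneRecord:
    """One secondary contact between two lineages.

    ``transition_category`` is ordered by the amount of admixture at the
    contact: ``no_gene_flow < steep < wide``.
    """

    node: str
    region: str
    species_pair: str
    divergence_ma: float
    contact_epoch: str
    transition_category: str

    def __post_init__(self) -> None:
        if self.divergence_ma <= 0:
            raise ValueError("divergence must be positive (Ma)")
        if self.contact_epoch not in CONTACT_EPOCHS:
            raise ValueError(f"unknown contact epoch {self.contact_epoch!r}")
        if self.transition_category not in TRANSITION_CATEGORIES:
            raise ValueError(f"unknown transition category {self.transition_category!r}")

    @property
    def category_rank(self) -> int:
        """0 = no gene flow, 1 = steep, 2 = wide."""
        return TRANSITION_CATEGORIES.index(self.transition_category)

    @property
    def post_lgm_contact(self) -> bool:
        """True for Holocene/Anthropocene contacts (Antiquity, 1950s, post-glacial)."""
        return self.contact_epoch != ">=LGM"


# ---------------------------------------------------------------------------
# STRUCTURE-style two-row format


def write_structure_format(gm: GenotypeMatrix, path) -> None:
    """Write a STRUCTURE-style file: header of locus names, two rows per
    individual (``id pop a1 ... aL``), missing coded as -9."""
    with open(path, "w") as fh:
        fh.write("\t".join(gm.loci) + "\n")
        for i, (ind, pop) in enumerate(zip(gm.ids, gm.pops)):
            for copy in (0, 1):
                row = gm.calls[i, :, copy].copy()
                row[row == MISSING] = STRUCTURE_MISSING
                fh.write("\t".join([ind, pop] + [str(a) for a in row]) + "\n")


def read_structure_format(path, ploidy: int = 2) -> GenotypeMatrix:
    """Read a STRUCTURE-style two-row-per-individual genotype file.

    Round-trips exactly with :func:`write_structure_format`.  Malformed
    files (ragged rows, an odd number of rows for an individual,
    non-integer allele codes) raise :class:`GenotypeParseError` naming the
    offending line or individual.
    """
    if ploidy != 2:
        raise ValueError("only diploid (ploidy=2) files are supported")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise GenotypeParseError(f"{path}: empty file")
    loci = lines[0].split("\t")
    n_loci = len(loci)
    rows: list[tuple[str, str, list[int]]] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != n_loci + 2:
            raise GenotypeParseError(
                f"{path}:{lineno}: expected {n_loci + 2} fields, got {len(parts)}"
            )
        ind, pop = parts[0], parts[1]
        try:
            alleles = [int(a) for a in parts[2:]]
        except ValueError as exc:
            raise GenotypeParseError(f"{path}:{lineno}: non-integer allele code") from exc
        rows.append((ind, pop, alleles))

    ids: list[str] = []
    pops: list[str] = []
    calls_list: list[np.ndarray] = []
    i = 0
    while i < len(rows):
        ind, pop, a1 = rows[i]
        run = 1
        while i + run < len(rows) and rows[i + run][0] == ind:
            run += 1
        if run != ploidy:
            raise GenotypeParseError(
                f"{path}: individual {ind!r} has {run} rows, expected {ploidy}"
            )
        _, pop2, a2 = rows[i + 1]
        if pop2 != pop:
            raise GenotypeParseError(
                f"{path}: individual {ind!r} has inconsistent population labels"
            )
        geno = np.stack([a1, a2], axis=-1)
        geno[geno == STRUCTURE_MISSING] = MISSING
        ids.append(ind)
        pops.append(pop)
        calls_list.append(geno)
        i += ploidy
    return GenotypeMatrix(ids=ids, pops=pops, loci=loci, calls=np.stack(calls_list))


# ---------------------------------------------------------------------------
# long-format delimited table


def write_long_table(gm: GenotypeMatrix, path) -> None:
    """Write genotypes as a long table: individual, population, locus, allele_1, allele_2."""
    recs = []
    for i, (ind, pop) in enumerate(zip(gm.ids, gm.pops)):
        for l, locus in enumerate(gm.loci):
            recs.append((ind, pop, locus, gm.calls[i, l, 0], gm.calls[i, l, 1]))
    pd.DataFrame(
        recs, columns=["individual", "population", "locus", "allele_1", "allele_2"]
    ).to_csv(path, sep="\t", index=False)


def read_long_table(path) -> GenotypeMatrix:
    """Read a long-format genotype table written by :func:`write_long_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "population": str, "locus": str})
    required = {"individual", "population", "locus", "allele_1", "allele_2"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    ids = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    ind_index = {v: i for i, v in enumerate(ids)}
    loc_index = {v: i for i, v in enumerate(loci)}
    calls = np.full((len(ids), len(loci), 2), MISSING, dtype=np.int64)
    pops = [""] * len(ids)
    for row in df.itertuples(index=False):
        i = ind_index[row.individual]
        l = loc_index[row.locus]
        pops[i] = row.population
        calls[i, l, 0] = int(row.allele_1)
        calls[i, l, 1] = int(row.allele_2)
    return GenotypeMatrix(ids=ids, pops=pops, loci=loci, calls=calls)


# ---------------------------------------------------------------------------
# locality and haplotype tables


def read_locality_table(path) -> LocalityTable:
    """Read a delimited locality table with columns
    locality, latitude, longitude[, n, on_transect]."""
    df = pd.read_csv(path, sep="\t", dtype={"locality": str})
    locs = []
    for row in df.itertuples(index=False):
        locs.append(
            Locality(
                locality_id=row.locality,
                latitude=float(row.latitude),
                longitude=float(row.longitude),
                n=int(getattr(row, "n", 0) or 0),
                on_transect=bool(getattr(row, "on_transect", True)),
            )
        )
    return LocalityTable(locs)


def write_locality_table(table: LocalityTable, path) -> None:
    pd.DataFrame(
        [
            (loc.locality_id, loc.latitude, loc.longitude, loc.n, loc.on_transect)
            for loc in table
        ],
        columns=["locality", "latitude", "longitude", "n", "on_transect"],
    ).to_csv(path, sep="\t", index=False)


def read_haplotype_table(path) -> pd.DataFrame:
    """Read a per-locality haplotype count table: locality, focal_count, total."""
    df = pd.read_csv(path, sep="\t", dtype={"locality": str})
    required = {"locality", "focal_count", "total"}
    if not required.issubset(df.columns):
        raise GenotypeParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if (df["focal_count"] > df["total"]).any() or (df["focal_count"] < 0).any():
        raise GenotypeParseError(f"{path}: focal_count must lie in [0, total]")
    return df


# ---------------------------------------------------------------------------
# contact-zone fixture


def load_contact_zone_fixture() -> list[ContactZoneRecord]:
    """Load the packaged table of ten Western-Palearctic tree-frog contact zones."""
    ref = importlib.resources.files("clinekit.data").joinpath("contact_zones.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"node": str})
    return [
        ContactZoneRecord(
            node=row.node,
            region=row.region,
            species_pair=row.species_pair,
            divergence_ma=float(row.divergence_ma),
            contact_epoch=row.contact_epoch,
            transition_category=row.transition_category,
        )
        for row in df.itertuples(index=False)
    ]


def read_contact_zone_table(path) -> list[ContactZoneRecord]:
    """Read a user-supplied contact-zone table with the packaged fixture's schema."""
    df = pd.read_csv(path, sep="\t", dtype={"node": str})
    records = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                ContactZoneRecord(
                    node=row.node,
                    region=row.region,
                    species_pair=row.species_pair,
                    divergence_ma=float(row.divergence_ma),
                    contact_epoch=row.contact_epoch,
                    transition_category=row.transition_category,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx}: {exc}") from exc
    return records


# ---------------------------------------------------------------------------
# transect geometry


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance (km) on a sphere of mean Earth radius."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def transect_distances(
    localities: LocalityTable, origin_rule: str = "northernmost"
) -> dict[str, float]:
    """Map transect localities to km positions along the transect.

    The origin (0 km) is the northernmost transect locality by default, or a
    named locality id.  Positions are great-circle distances from the origin,
    not cumulative path lengths, so they are reproducible regardless of
    locality ordering.  Violations of latitude-monotonicity (distance order
    disagreeing with north-to-south order) are reported as warnings.
    """
    transect = localities.transect()
    if not transect:
        raise ValueError("no transect localities")
    if len(transect) < 2:
        raise ValueError("need at least two transect localities")
    if origin_rule == "northernmost":
        origin = max(transect, key=lambda loc: loc.latitude)
    else:
        matches = [loc for loc in transect if loc.locality_id == origin_rule]
        if not matches:
            raise ValueError(f"origin locality {origin_rule!r} not on transect")
        origin = matches[0]
    dist = {
        loc.locality_id: haversine_km(
            origin.latitude, origin.longitude, loc.latitude, loc.longitude
        )
        for loc in transect
    }
    # monotonicity check against latitude order (warn, do not fail)
    by_lat = sorted(transect, key=lambda loc: -loc.latitude)
    d_sorted = [dist[loc.locality_id] for loc in by_lat]
    violations = [
        (by_lat[i].locality_id, by_lat[i + 1].locality_id)
        for i in range(len(d_sorted) - 1)
        if d_sorted[i] > d_sorted[i + 1] + 1e-9
    ]
    if violations:
        import warnings

        warnings.warn(
            f"transect distances not monotone with latitude for pairs {violations}; "
            "the transect may bend",
            stacklevel=2,
        )
    return dist
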