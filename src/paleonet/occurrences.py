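"""Reading, validation, filtering and reshaping of fossil occurrence data.

An occurrence is a (taxon, collection point) pair: a report of a body genus or
ichnogenus at a stratigraphically and geographically distinct locality.
Collection points belong to geologic formations; taxa carry taphonomic and
morphologic metadata plus a set of paleoenvironment codes. Downstream stages
consume either the normalized :class:`OccurrenceTable` or the presence/absence
:class:`IncidenceMatrix` built from it.
"""
from __future__ import annotations

import json
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd

from .errors import InputDataError, ParameterError, SchemaError

BODY_GENUS = "body_genus"
ICHNOGENUS = "ichnogenus"

#: Taxa carrying any of these flags are dropped by the default filter policy:
#: simple discs, putative taphomorphs and putative pseudofossils cannot serve
#: as index fossils.
DEFAULT_FLAG_EXCLUSIONS = frozenset(
    {"disc_shaped", "possible_taphomorph", "possible_pseudofossil"}
)


@dataclass(frozen=True)
class Taxon:
    """A body genus or ichnogenus with its metadata.

    Exactly one of ``morphogroup`` (body taxa) / ``trace_architecture``
    (ichnogenera) should be set; a mismatch with ``kind`` is a validation
    error, a missing value only a reportable issue.
    """

    name: str
    kind: str = BODY_GENUS
    preservational_mode: str | None = None
    morphogroup: str | None = None
    trace_architecture: str | None = None
    form_category: str | None = None
    paleocommunity: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind not in (BODY_GENUS, ICHNOGENUS):
            raise InputDataError(f"unknown taxon kind {self.kind!r}")
        if self.kind == BODY_GENUS and self.trace_architecture is not None:
            raise InputDataError(
                f"body genus {self.name!r} must not set trace_architecture"
            )
        if self.kind == ICHNOGENUS and self.morphogroup is not None:
            raise InputDataError(
                f"ichnogenus {self.name!r} must not set morphogroup"
            )


@dataclass(frozen=True)
class CollectionPoint:
    """A unique point in geographic and stratigraphic space."""

    id: str
    formation: str
    lat: float = float("nan")
    lon: float = float("nan")
    country: str = ""
    region: str = ""
    geoplate: str = ""

    def __post_init__(self) -> None:
        if not self.formation:
            raise InputDataError(
                f"collection point {self.id!r} has no formation"
            )


@dataclass
class ColumnSchema:
    """Mapping from logical fields to CSV column names.

    ``taxon``, ``collection_id`` and ``formation`` are required; all other
    columns are optional and default to the documented interchange names.
    Multi-valued columns (``environments``, ``flags``) hold
    semicolon-separated codes.
    """

    taxon: str = "taxon"
    taxon_kind: str = "taxon_kind"
    collection_id: str = "collection_id"
    formation: str = "formation"
    lat: str = "lat"
    lon: str = "lon"
    country: str = "country"
    region: str = "region"
    geoplate: str = "geoplate"
    environments: str = "environments"
    preservational_mode: str = "preservational_mode"
    morphogroup_or_architecture: str = "morphogroup_or_architecture"
    form_category: str = "form_category"
    paleocommunity: str = "paleocommunity"
    flags: str = "flags"

    required = ("taxon", "collection_id", "formation")


@dataclass
class OccurrenceTable:
    """Normalized occurrence records with taxon and locality registries."""

    taxa: dict[str, Taxon]
    points: dict[str, CollectionPoint]
    occurrences: list[tuple[str, str]]  # (taxon name, collection point id)
    taxon_environments: dict[str, set[str]] = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    # -- registries -----------------------------------------------------
    @property
    def formations(self) -> dict[str, list[str]]:
        """Formation name -> list of its collection point ids."""
        out: dict[str, list[str]] = defaultdict(list)
        for pid in self.points:
            out[self.points[pid].formation].append(pid)
        return dict(out)

    def taxa_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, t in self.taxa.items() if t.kind == kind)

    @property
    def n_occurrences(self) -> int:
        return len(self.occurrences)

    def validate(self) -> None:
        """Raise on any violated structural invariant."""
        seen: set[tuple[str, str]] = set()
        for taxon, pid in self.occurrences:
            if taxon not in self.taxa:
                raise InputDataError(f"occurrence references unknown taxon {taxon!r}")
            if pid not in self.points:
                raise InputDataError(f"occurrence references unknown point {pid!r}")
            if (taxon, pid) in seen:
                raise InputDataError(f"duplicate occurrence {(taxon, pid)!r}")
            seen.add((taxon, pid))
        for name in self.taxon_environments:
            if name not in self.taxa:
                raise InputDataError(
                    f"environment assignment for unknown taxon {name!r}"
                )

    # -- serialization --------------------------------------------------
    def to_frame(self, schema: ColumnSchema | None = None) -> pd.DataFrame:
        """One row per occurrence in the interchange CSV schema."""
        schema = schema or ColumnSchema()
        rows = []
        for taxon, pid in self.occurrences:
            t = self.taxa[taxon]
            p = self.points[pid]
            rows.append(
                {
                    schema.taxon: taxon,
                    schema.taxon_kind: t.kind,
                    schema.collection_id: pid,
                    schema.formation: p.formation,
                    schema.lat: p.lat,
                    schema.lon: p.lon,
                    schema.country: p.country,
                    schema.region: p.region,
                    schema.geoplate: p.geoplate,
                    schema.environments: ";".join(
                        sorted(self.taxon_environments.get(taxon, set()))
                    ),
                    schema.preservational_mode: t.preservational_mode or "",
                    schema.morphogroup_or_architecture: (
                        t.morphogroup or t.trace_architecture or ""
                    ),
                    schema.form_category: t.form_category or "",
                    schema.paleocommunity: t.paleocommunity or "",
                    schema.flags: ";".join(sorted(t.flags)),
                }
            )
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _split_multi(value) -> set[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return set()
    parts = str(value).split(";")
    return {p.strip() for p in parts if p.strip()}


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def read_occurrences(
    source,
    schema: ColumnSchema | None = None,
    vocabulary: dict[str, list[str]] | None = None,
) -> OccurrenceTable:
    """Read and normalize an occurrence CSV.

    Duplicate (taxon, point) rows collapse to a single occurrence;
    per-occurrence environment codes are unioned into each taxon's
    environment set. Codes absent from the vocabulary (when one is given)
    are collected in ``table.report["unknown_codes"]`` rather than rejected.

    Raises
    ------
    SchemaError
        if a required column is missing.
    InputDataError
        if the table is empty or a point lacks a formation.
    """
    schema = schema or ColumnSchema()
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source, dtype=str)
    elif isinstance(source, pd.DataFrame):
        df = source.astype(object)
    else:  # file-like stream
        df = pd.read_csv(source, dtype=str)

    missing = [
        getattr(schema, f) for f in schema.required
        if getattr(schema, f) not in df.columns
    ]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    if len(df) == 0:
        raise InputDataError("empty occurrence table")

    taxa: dict[str, Taxon] = {}
    points: dict[str, CollectionPoint] = {}
    occurrences: list[tuple[str, str]] = []
    environments: dict[str, set[str]] = defaultdict(set)
    seen: set[tuple[str, str]] = set()
    duplicates = 0
    unknown_codes: set[str] = set()

    def col(row, name, default=None):
        cname = getattr(schema, name)
        if cname in df.columns:
            return row[cname]
        return default

    for _, row in df.iterrows():
        name = str(row[schema.taxon]).strip()
        pid = str(row[schema.collection_id]).strip()
        formation = _opt(col(row, "formation"))
        if not formation:
            raise InputDataError(
                f"collection point {pid!r} has no formation"
            )
        if pid not in points:
            points[pid] = CollectionPoint(
                id=pid,
                formation=formation,
                lat=float(col(row, "lat", "nan") or "nan"),
                lon=float(col(row, "lon", "nan") or "nan"),
                country=_opt(col(row, "country")) or "",
                region=_opt(col(row, "region")) or "",
                geoplate=_opt(col(row, "geoplate")) or "",
            )
        if name not in taxa:
            kind = _opt(col(row, "taxon_kind")) or BODY_GENUS
            group = _opt(col(row, "morphogroup_or_architecture"))
            taxa[name] = Taxon(
                name=name,
                kind=kind,
                preservational_mode=_opt(col(row, "preservational_mode")),
                morphogroup=group if kind == BODY_GENUS else None,
                trace_architecture=group if kind == ICHNOGENUS else None,
                form_category=_opt(col(row, "form_category")),
                paleocommunity=_opt(col(row, "paleocommunity")),
                flags=frozenset(_split_multi(col(row, "flags"))),
            )
        environments[name] |= _split_multi(col(row, "environments"))
        if (name, pid) in seen:
            duplicates += 1
            continue
        seen.add((name, pid))
        occurrences.append((name, pid))

    if vocabulary is not None:
        env_codes = set(vocabulary.get("paleoenvironments", []))
        mode_codes = set(vocabulary.get("preservational_modes", []))
        for envs in environments.values():
            unknown_codes |= envs - env_codes
        for t in taxa.values():
            if t.preservational_mode and t.preservational_mode not in mode_codes:
                unknown_codes.add(t.preservational_mode)

    table = OccurrenceTable(
        taxa=taxa,
        points=points,
        occurrences=occurrences,
        taxon_environments={k: set(v) for k, v in environments.items()},
        report={
            "duplicate_rows_collapsed": duplicates,
            "unknown_codes": sorted(unknown_codes),
        },
    )
    table.validate()
    return table


@dataclass
class FilterPolicy:
    """Index-taxon retention policy.

    A retained taxon (i) carries none of ``exclude_flags``, (ii) is not named
    in ``exclude_taxa`` (a configurable exclusion list, e.g. for known disc
    form-taxa), and (iii) co-occurs with at least one other retained taxon at
    some collection point or within some formation, so that it can be linked
    in the networks.
    """

    exclude_flags: frozenset[str] = DEFAULT_FLAG_EXCLUSIONS
    exclude_taxa: frozenset[str] = frozenset()
    require_cooccurrence: bool = True


def filter_index_taxa(
    table: OccurrenceTable, policy: FilterPolicy | None = None
) -> tuple[OccurrenceTable, dict]:
    """Apply the index-taxon criteria; returns the filtered table + report.

    The co-occurrence criterion is applied to a fixed point (removal of one
    taxon may isolate another), which makes the operation idempotent.
    """
    policy = policy or FilterPolicy()
    removed_flags = sorted(
        n for n, t in table.taxa.items()
        if (t.flags & policy.exclude_flags) or n in policy.exclude_taxa
    )
    retained = set(table.taxa) - set(removed_flags)

    removed_isolated: set[str] = set()
    if policy.require_cooccurrence:
        by_point: dict[str, set[str]] = defaultdict(set)
        by_formation: dict[str, set[str]] = defaultdict(set)
        for taxon, pid in table.occurrences:
            by_point[pid].add(taxon)
            by_formation[table.points[pid].formation].add(taxon)
        while True:
            drop = set()
            for taxon in retained:
                linked = False
                for group in (by_point, by_formation):
                    for members in group.values():
                        if taxon in members and len(members & retained) > 1:
                            linked = True
                            break
                    if linked:
                        break
                if not linked:
                    drop.add(taxon)
            if not drop:
                break
            retained -= drop
            removed_isolated |= drop

    occurrences = [(t, p) for t, p in table.occurrences if t in retained]
    point_ids = {p for _, p in occurrences}
    new = OccurrenceTable(
        taxa={n: table.taxa[n] for n in retained},
        points={p: table.points[p] for p in point_ids},
        occurrences=occurrences,
        taxon_environments={
            n: set(v) for n, v in table.taxon_environments.items()
            if n in retained
        },
    )
    report = {
        "removed_flagged": removed_flags,
        "removed_isolated": sorted(removed_isolated),
        "n_retained": len(retained),
    }
    if not retained:
        report["warning"] = "no taxa retained by filter"
    new.report = dict(new.report, **report)
    return new, report


@dataclass
class IncidenceMatrix:
    """Taxa x samples presence/absence with incidence bookkeeping.

    ``Y[i]`` is the number of samples containing taxon *i*; ``Q[j]`` the
    number of taxa found in exactly *j* samples. The identities
    ``sum_j j*Q_j == sum_i Y_i`` and ``S_obs == sum_j Q_j`` hold by
    construction.
    """

    data: pd.DataFrame  # bool, index = taxa, columns = samples
    sample_unit: str = "collection_point"

    def __post_init__(self) -> None:
        self.data = self.data.astype(bool)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def N(self) -> int:
        return self.data.shape[1]

    @property
    def S_obs(self) -> int:
        return int((self.data.sum(axis=1) > 0).sum())

    @property
    def Y(self) -> pd.Series:
        """Incidence frequency of every taxon (number of samples)."""
        return self.data.sum(axis=1).astype(int)

    @property
    def Q(self) -> dict[int, int]:
        """Incidence frequency counts: Q[j] = #taxa in exactly j samples."""
        counts = self.Y.value_counts()
        return {int(j): int(c) for j, c in counts.items() if j > 0}

    def q(self, j: int) -> int:
        return self.Q.get(j, 0)

    def subset_samples(self, samples: Iterable[str]) -> "IncidenceMatrix":
        sub = self.data.loc[:, list(samples)]
        sub = sub.loc[sub.sum(axis=1) > 0]
        return IncidenceMatrix(sub, sample_unit=self.sample_unit)

    def write_csv(self, path: str | Path) -> None:
        self.data.astype(int).to_csv(path)


def build_incidence(
    table: OccurrenceTable,
    sample_unit: Literal["collection_point", "formation"] = "collection_point",
    taxa_subset: Iterable[str] | None = None,
) -> IncidenceMatrix:
    """Build the presence/absence matrix over collection points or formations.

    Taxa with zero incidences (e.g. after subsetting) are dropped.
    """
    if taxa_subset is not None:
        keep = set(taxa_subset)
    else:
        keep = set(table.taxa)
    pairs: set[tuple[str, str]] = set()
    for taxon, pid in table.occurrences:
        if taxon not in keep:
            continue
        sample = (
            pid if sample_unit == "collection_point"
            else table.points[pid].formation
        )
        pairs.add((taxon, sample))
    if not pairs:
        raise InputDataError("empty selection: no occurrences match")
    taxa = sorted({t for t, _ in pairs})
    samples = sorted({s for _, s in pairs})
    mat = pd.DataFrame(False, index=taxa, columns=samples)
    for t, s in pairs:
        mat.loc[t, s] = True
    return IncidenceMatrix(mat, sample_unit=sample_unit)


def select_formations(
    incidence: IncidenceMatrix, min_taxa: int
) -> IncidenceMatrix:
    """Retain formation samples containing at least ``min_taxa`` taxa."""
    if min_taxa < 1:
        raise ParameterError("min_taxa must be >= 1")
    if incidence.sample_unit != "formation":
        raise ParameterError(
            "select_formations requires a formation-level incidence matrix"
        )
    richness = incidence.data.sum(axis=0)
    kept = richness[richness >= min_taxa].index
    if len(kept) == 0:
        raise InputDataError(
            f"no formation holds >= {min_taxa} taxa"
        )
    return incidence.subset_samples(kept)


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
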