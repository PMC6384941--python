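"""Synthetic fossil occurrence datasets with planted structure.

The generator emulates the shape of a global occurrence compilation:
``n_biozones`` groups of formations whose taxon pools partially overlap
(biozones, the stratigraphic signal), an ordered depth gradient of
paleoenvironments with taxon preference windows (biotopes, the ecological
signal), collection points nested in formations, and per-collection
detection probability (sampling noise). Planted labels are returned as
:class:`GroundTruth` so every downstream stage can be scored for recovery.

The default configuration loosely mirrors a global Ediacaran-scale
compilation: 4 biozones, ~40 formations, ~150 taxa, ~600 collection points.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputDataError, ParameterError
from .occurrences import (
    BODY_GENUS,
    ICHNOGENUS,
    CollectionPoint,
    OccurrenceTable,
    Taxon,
)
from .validation import nmi
from .vocabulary import load_vocabulary

DEFAULT_BIOTOPES = {
    "shallow": (0, 1),
    "intermediate": (2, 3),
    "deep": (4, 5),
}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults define the reference study conditions."""

    n_biozones: int = 4
    formations_per_biozone: int = 10
    taxon_pool_size_per_biozone: int | tuple = 38
    cross_biozone_shared_fraction: float = 0.10
    n_environments: int = 6
    #: biotope label -> inclusive (lo, hi) window on the environment gradient
    biotope_assignment: dict = field(
        default_factory=lambda: dict(DEFAULT_BIOTOPES)
    )
    collections_per_formation: tuple = (10, 20)
    taxa_per_collection: tuple = (3, 9)
    detection_probability: float = 0.9
    ichnogenus_fraction: float = 0.15
    flagged_fraction: float = 0.05
    seed: int = 0

    def pool_sizes(self) -> list[int]:
        if isinstance(self.taxon_pool_size_per_biozone, int):
            return [self.taxon_pool_size_per_biozone] * self.n_biozones
        sizes = list(self.taxon_pool_size_per_biozone)
        if len(sizes) != self.n_biozones:
            raise ParameterError(
                "taxon_pool_size_per_biozone must be an int or one size per biozone"
            )
        return sizes

    def validate(self) -> None:
        if self.n_biozones < 2:
            raise ParameterError("need >= 2 biozones for comparison analyses")
        if not (0 <= self.cross_biozone_shared_fraction <= 1):
            raise ParameterError("cross_biozone_shared_fraction outside [0,1]")
        if not (0 < self.detection_probability <= 1):
            raise ParameterError("detection_probability outside (0,1]")
        if min(self.pool_sizes()) < 1:
            raise InputDataError("empty taxon pool in config")
        for lo, hi in self.biotope_assignment.values():
            if not (0 <= lo <= hi < self.n_environments):
                raise ParameterError("biotope window outside environment gradient")


@dataclass
class GroundTruth:
    """Planted labels consistent with the generated table."""

    taxon_biozones: dict  # taxon -> list of biozone labels (primary first)
    taxon_biotope: dict  # taxon -> biotope label
    formation_biozone: dict  # formation -> biozone label
    intended_richness: dict  # biozone -> taxon pool size

    def primary_biozone(self, taxon: str) -> str:
        return self.taxon_biozones[taxon][0]

    def biozone_labels(self, nodes) -> dict:
        """Crisp biozone label per node (taxa: primary; formations: own)."""
        out = {}
        for n in nodes:
            if n in self.formation_biozone:
                out[n] = self.formation_biozone[n]
            elif n in self.taxon_biozones:
                out[n] = self.primary_biozone(n)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "taxon_biozones": self.taxon_biozones,
                    "taxon_biotope": self.taxon_biotope,
                    "formation_biozone": self.formation_biozone,
                    "intended_richness": self.intended_richness,
                },
                indent=2,
                sort_keys=True,
            )
        )


def generate(config: SyntheticConfig | None = None) -> tuple[OccurrenceTable, GroundTruth]:
    """Draw one synthetic occurrence dataset; deterministic under the seed."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab = load_vocabulary()
    envs = vocab["paleoenvironments"][: config.n_environments]
    biotopes = sorted(config.biotope_assignment)
    communities = vocab["paleocommunities"]
    pool_sizes = config.pool_sizes()

    # --- taxon pools per biozone, with cross-biozone sharing -----------
    taxon_biozones: dict[str, list[str]] = {}
    taxon_biotope: dict[str, str] = {}
    pools: dict[str, list[str]] = {}
    bz_labels = [f"BZ{k + 1}" for k in range(config.n_biozones)]
    for k, bz in enumerate(bz_labels):
        pools[bz] = []
        for i in range(pool_sizes[k]):
            name = f"Taxon_{bz}_{i + 1:03d}"
            pools[bz].append(name)
            taxon_biozones[name] = [bz]
            taxon_biotope[name] = biotopes[int(rng.integers(len(biotopes)))]
    for k in range(config.n_biozones - 1):
        src, dst = bz_labels[k], bz_labels[k + 1]
        n_share = int(np.floor(config.cross_biozone_shared_fraction * pool_sizes[k]))
        if n_share:
            shared = rng.choice(pools[src], size=n_share, replace=False)
            for name in shared:
                pools[dst].append(str(name))
                taxon_biozones[str(name)].append(dst)

    # --- taxon metadata: biozone-biased preservational modes -----------
    modes = vocab["preservational_modes"]
    morphs = vocab["morphogroups"]
    archs = vocab["trace_architectures"]
    forms = vocab["form_categories"]
    mode_bias = {
        bz: rng.dirichlet(np.full(len(modes), 0.4)) for bz in bz_labels
    }
    taxa: dict[str, Taxon] = {}
    for name, bzs in taxon_biozones.items():
        is_trace = rng.random() < config.ichnogenus_fraction
        kind = ICHNOGENUS if is_trace else BODY_GENUS
        flags = []
        if rng.random() < config.flagged_fraction:
            flags.append(
                str(rng.choice(
                    ["disc_shaped", "possible_taphomorph", "possible_pseudofossil"]
                ))
            )
        taxa[name] = Taxon(
            name=name,
            kind=kind,
            preservational_mode=str(rng.choice(modes, p=mode_bias[bzs[0]])),
            morphogroup=None if is_trace else str(rng.choice(morphs)),
            trace_architecture=str(rng.choice(archs)) if is_trace else None,
            form_category=str(rng.choice(forms)),
            paleocommunity=communities[
                bz_labels.index(bzs[0]) % len(communities)
            ],
            flags=frozenset(flags),
        )

    # --- formations, collections, occurrences --------------------------
    collection_envs: dict[str, int] = {}
    points: dict[str, CollectionPoint] = {}
    occurrences: list[tuple[str, str]] = []
    formation_biozone: dict[str, str] = {}
    countries = ["Arcadia", "Borealia", "Cimmeria", "Doggerland"]
    for k, bz in enumerate(bz_labels):
        for j in range(config.formations_per_biozone):
            fm = f"Fm_{bz}_{j + 1:02d}"
            formation_biozone[fm] = bz
            # each formation spans a contiguous environment window
            span = int(rng.integers(2, max(3, config.n_environments)))
            lo = int(rng.integers(0, config.n_environments - span + 1))
            fm_envs = list(range(lo, lo + span))
            n_coll = int(rng.integers(*config.collections_per_formation))
            country = str(rng.choice(countries))
            for c in range(n_coll):
                pid = f"{fm}_c{c + 1:03d}"
                env = int(rng.choice(fm_envs))
                collection_envs[pid] = env
                points[pid] = CollectionPoint(
                    id=pid,
                    formation=fm,
                    lat=float(np.round(rng.uniform(-60, 60), 4)),
                    lon=float(np.round(rng.uniform(-180, 180), 4)),
                    country=country,
                    region=country,
                    geoplate=f"plate_{country[:3].lower()}",
                )
                # taxa compatible with this collection's environment
                candidates = [
                    t for t in pools[bz]
                    if _window_contains(
                        config.biotope_assignment[taxon_biotope[t]], env
                    )
                ]
                if not candidates:
                    continue
                size = min(
                    int(rng.integers(*config.taxa_per_collection)),
                    len(candidates),
                )
                drawn = rng.choice(candidates, size=size, replace=False)
                for t in drawn:
                    if rng.random() <= config.detection_probability:
                        occurrences.append((str(t), pid))

    occurrences = sorted(set(occurrences))
    present = {t for t, _ in occurrences}
    # environment sets derive from realized occurrences: the environments of
    # the collections where each taxon was actually found
    taxon_environments: dict[str, set[str]] = {t: set() for t in present}
    for t, pid in occurrences:
        taxon_environments[t].add(envs[collection_envs[pid]])
    table = OccurrenceTable(
        taxa={t: taxa[t] for t in present},
        points={p: points[p] for p in {pid for _, pid in occurrences}},
        occurrences=occurrences,
        taxon_environments=taxon_environments,
    )
    truth = GroundTruth(
        taxon_biozones={t: taxon_biozones[t] for t in present},
        taxon_biotope={t: taxon_biotope[t] for t in present},
        formation_biozone=formation_biozone,
        intended_richness={bz: len(pools[bz]) for bz in bz_labels},
    )
    table.validate()
    return table, truth


def _window_contains(window: tuple, env: int) -> bool:
    lo, hi = window
    return lo <= env <= hi


def recovery_score(pipeline_output, truth: GroundTruth, layer: str = "biozone") -> float:
    """NMI between detected communities and planted labels.

    Covers are crisped by maximum belonging coefficient. ``layer`` selects
    the planted labeling: ``biozone`` (taxa by primary biozone, formations
    by their own) or ``biotope`` (taxa only).
    """
    from .communities import Cover

    if isinstance(pipeline_output, Cover):
        detected = pipeline_output.to_partition()
    else:
        detected = dict(pipeline_output)
    if layer == "biozone":
        planted = truth.biozone_labels(detected)
    elif layer == "biotope":
        planted = {
            n: truth.taxon_biotope[n]
            for n in detected if n in truth.taxon_biotope
        }
    else:
        raise ParameterError(f"unknown layer {layer!r}")
    shared = set(detected) & set(planted)
    if not shared:
        raise InputDataError("no nodes shared between output and ground truth")
    return nmi(
        {n: detected[n] for n in shared},
        {n: planted[n] for n in shared},
        universe=shared,
    )
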