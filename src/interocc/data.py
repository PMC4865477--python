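"""Core data structures and I/O for multi-species camera-trap detection histories.

The survey layout is a set of camera sites grouped into spatial arrays, each
site observed over a fixed number of survey occasions.  Detection histories are
binary site x occasion records per species; occasions where a camera was not
operating are missing, not zero.  Site covariates are either continuous
land-cover proportions (standardized before modelling) or binary trail
attributes (left untouched).

All file formats are plain delimited text (CSV):

* detection histories -- long format with columns ``species, site, occasion,
  detected``; active cells absent from the file are taken as 0.
* survey design -- one row per site with columns ``site, array,
  active_1 .. active_J`` (0/1 flags per occasion).
* covariates -- one row per site, ``site`` column plus one column per
  covariate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: Submodel kinds.
ABUNDANCE_RN = "abundance_RN"
OCCUPANCY = "occupancy"

#: Parameters an interaction can target.
STATE = "state"
DETECTION = "detection"

#: Latent quantities an interaction can read from its source species.
LATENT_N = "latent_N"
LATENT_Z = "latent_z"


class DataError(ValueError):
    """Raised when input files or containers violate the data contract."""


# ---------------------------------------------------------------------------
# survey design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SurveyDesign:
    """Site layout: array membership and per-occasion camera activity.

    Parameters
    ----------
    site_labels
        One label per site, in site-index order.
    array_of_site
        Integer array index (0-based, contiguous) per site.
    array_names
        Names of the arrays; ``len(array_names)`` is the number of arrays.
    active
        Boolean (n_sites, n_occasions) mask; True where the camera operated.
    """

    site_labels: tuple
    array_of_site: np.ndarray
    array_names: tuple
    active: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "array_of_site", np.asarray(self.array_of_site, dtype=np.intp))
        object.__setattr__(self, "active", np.asarray(self.active, dtype=bool))
        if self.active.ndim != 2 or self.active.shape[0] != len(self.site_labels):
            raise DataError("active mask must be (n_sites, n_occasions)")
        if self.array_of_site.shape != (len(self.site_labels),):
            raise DataError("array_of_site must have one entry per site")
        n_arrays = len(self.array_names)
        labels = np.unique(self.array_of_site)
        if labels.size and (labels.min() < 0 or labels.max() >= n_arrays):
            raise DataError("array indices out of range")
        if not np.array_equal(labels, np.arange(n_arrays)):
            raise DataError("array labels must form a contiguous index set with every array non-empty")
        dead = ~self.active.any(axis=1)
        if dead.any():
            bad = [self.site_labels[i] for i in np.flatnonzero(dead)]
            raise DataError(f"sites with zero active occasions: {bad}")

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def n_occasions(self) -> int:
        return self.active.shape[1]

    @property
    def n_arrays(self) -> int:
        return len(self.array_names)

    def site_index(self, label) -> int:
        return self.site_labels.index(label)

    def sites_in_array(self, a: int) -> np.ndarray:
        return np.flatnonzero(self.array_of_site == a)


@dataclass(frozen=True)
class DetectionData:
    """Binary detection histories for several species over one survey design.

    ``histories[species]`` is an int8 (n_sites, n_occasions) array with values
    0/1 where the camera was active and :data:`MISSING` (-1) exactly where it
    was not.
    """

    histories: dict
    design: SurveyDesign

    def __post_init__(self):
        for sp, h in self.histories.items():
            h = np.asarray(h, dtype=np.int8)
            self.histories[sp] = h
            if h.shape != (self.design.n_sites, self.design.n_occasions):
                raise DataError(f"history for {sp!r} has shape {h.shape}, expected "
                                f"{(self.design.n_sites, self.design.n_occasions)}")
            active = self.design.active
            if not np.all((h[~active] == MISSING)):
                raise DataError(f"history for {sp!r} has data in inactive cells")
            vals = h[active]
            if not np.isin(vals, [0, 1]).all():
                raise DataError(f"history for {sp!r} has non-binary values in active cells")

    @property
    def species(self) -> list:
        return list(self.histories)

    def detections(self, species: str) -> np.ndarray:
        """Per-site count of occasions with a detection (missing skipped)."""
        h = self.histories[species]
        return (h == 1).sum(axis=1)

    def effort(self) -> np.ndarray:
        """Per-site number of active occasions."""
        return self.design.active.sum(axis=1)

    def detected_anywhere(self, species: str) -> np.ndarray:
        return (self.histories[species] == 1).any(axis=1)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


@dataclass
class CovariateTable:
    """Per-site covariates: continuous (standardizable) and binary columns.

    ``transforms`` holds the (mean, sd) of the raw scale for each continuous
    covariate once standardized, so values can be mapped back.
    """

    continuous: dict
    binary: dict
    transforms: dict = field(default_factory=dict)

    def __post_init__(self):
        self.continuous = {k: np.asarray(v, dtype=float) for k, v in self.continuous.items()}
        self.binary = {k: np.asarray(v, dtype=float) for k, v in self.binary.items()}
        lengths = {v.shape[0] for v in (*self.continuous.values(), *self.binary.values())}
        if len(lengths) > 1:
            raise DataError(f"covariate columns of unequal length: {sorted(lengths)}")
        for k, v in self.binary.items():
            if not np.isin(v, [0.0, 1.0]).all():
                raise DataError(f"binary covariate {k!r} has values outside {{0,1}}")

    @property
    def names(self) -> list:
        return list(self.continuous) + list(self.binary)

    def column(self, name: str) -> np.ndarray:
        if name in self.continuous:
            return self.continuous[name]
        if name in self.binary:
            return self.binary[name]
        raise KeyError(name)

    def unstandardize(self, name: str, values: np.ndarray) -> np.ndarray:
        """Map standardized values of a continuous covariate back to raw scale."""
        mean, sd = self.transforms[name]
        return np.asarray(values) * (sd / 0.5) + mean


def standardize_covariates(table: CovariateTable) -> CovariateTable:
    """Rescale continuous covariates to mean 0, sd 0.5; pass binary through.

    The half-unit scaling puts continuous effects on a footing comparable to a
    0/1 dummy variable.  Idempotent: standardizing twice leaves values
    unchanged, and the raw-scale (mean, sd) pair is retained for back-mapping.

    Raises
    ------
    DataError
        If a continuous covariate has zero variance (names it).
    """
    out_cont, transforms = {}, {}
    for name, x in table.continuous.items():
        mean, sd = float(np.mean(x)), float(np.std(x))
        if sd == 0.0:
            raise DataError(f"continuous covariate {name!r} has zero variance")
        out_cont[name] = (x - mean) * (0.5 / sd)
        if name in table.transforms:
            # compose with the earlier transform so unstandardize still maps to raw
            m0, s0 = table.transforms[name]
            transforms[name] = (m0 + mean * (s0 / 0.5), sd * (s0 / 0.5))
        else:
            transforms[name] = (mean, sd)
    return CovariateTable(continuous=out_cont, binary=dict(table.binary), transforms=transforms)


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interaction:
    """A directed species-interaction edge.

    The realized latent state of ``source`` (site abundance N for a
    Royle-Nichols species, occurrence z for an occupancy species) enters the
    ``target_parameter`` linear predictor of ``target`` as a covariate.
    """

    source: str
    source_quantity: str  # LATENT_N or LATENT_Z
    target: str
    target_parameter: str  # STATE or DETECTION

    def label(self) -> str:
        return f"int:{self.source}"


@dataclass
class ModelSpec:
    """Declarative model description: submodels, candidate covariates, DAG.

    Attributes
    ----------
    species
        Ordered species labels.
    submodel_of_species
        Maps species -> :data:`ABUNDANCE_RN` or :data:`OCCUPANCY`.
    state_covariates, detection_covariates
        Maps species -> candidate covariate names for the state (lambda or
        psi) and detection (r or p) predictors.
    interactions
        Directed edges; must form a DAG over species.
    selection_enabled
        Whether coefficients carry Gibbs-variable-selection indicators.
    random_intercepts
        Whether every linear predictor gets an array-level random intercept.
    """

    species: list
    submodel_of_species: dict
    state_covariates: dict
    detection_covariates: dict
    interactions: list = field(default_factory=list)
    selection_enabled: bool = True
    random_intercepts: bool = True

    def interactions_into(self, species: str, parameter: str) -> list:
        return [e for e in self.interactions
                if e.target == species and e.target_parameter == parameter]

    def covariates_of(self, species: str, parameter: str) -> list:
        m = self.state_covariates if parameter == STATE else self.detection_covariates
        return list(m.get(species, []))


def topological_order(spec: ModelSpec) -> list:
    """Order species so every interaction source precedes its targets.

    Ties are broken by the order of ``spec.species``.  Raises
    :class:`DataError` listing a cycle if the interaction graph is not acyclic.
    """
    deps = {s: set() for s in spec.species}
    for e in spec.interactions:
        deps[e.target].add(e.source)
    order, placed = [], set()
    pending = list(spec.species)
    while pending:
        progressed = False
        for s in list(pending):
            if deps[s] <= placed:
                order.append(s)
                placed.add(s)
                pending.remove(s)
                progressed = True
        if not progressed:
            cycle = sorted(pending)
            raise DataError(f"interaction graph has a cycle among {cycle}")
    return order


def validate_spec(spec: ModelSpec, data: DetectionData | None = None,
                  covs: CovariateTable | None = None) -> list:
    """Check a model specification against data and covariates.

    Returns a list of human-readable findings; an empty list means the spec is
    usable.  A cyclic interaction graph raises :class:`DataError` because no
    sampling order exists at all.
    """
    findings = []
    for s in spec.species:
        if s not in spec.submodel_of_species:
            findings.append(f"species {s!r} has no submodel")
        elif spec.submodel_of_species[s] not in (ABUNDANCE_RN, OCCUPANCY):
            findings.append(f"species {s!r} has unknown submodel "
                            f"{spec.submodel_of_species[s]!r}")
    for e in spec.interactions:
        if e.source == e.target:
            findings.append(f"self-edge on species {e.source!r}")
        for sp in (e.source, e.target):
            if sp not in spec.species:
                findings.append(f"interaction references unknown species {sp!r}")
        sub = spec.submodel_of_species.get(e.source)
        want = LATENT_N if sub == ABUNDANCE_RN else LATENT_Z
        if sub is not None and e.source_quantity != want:
            findings.append(
                f"interaction {e.source}->{e.target}: source_quantity "
                f"{e.source_quantity!r} inconsistent with {sub!r} submodel")
        if e.target_parameter not in (STATE, DETECTION):
            findings.append(f"interaction {e.source}->{e.target}: unknown target "
                            f"parameter {e.target_parameter!r}")
    topological_order(spec)  # raises on a cycle
    if covs is not None:
        known = set(covs.names)
        for cmap in (spec.state_covariates, spec.detection_covariates):
            for sp, names in cmap.items():
                for name in names:
                    if name not in known:
                        findings.append(f"covariate {name!r} for species {sp!r} "
                                        "missing from covariate table")
    if data is not None:
        for s in spec.species:
            if s not in data.histories:
                findings.append(f"no detection history for species {s!r}")
    return findings


def spec_to_dict(spec: ModelSpec) -> dict:
    """Serialize a ModelSpec to plain data (YAML/JSON-friendly)."""
    return {
        "species": list(spec.species),
        "submodels": dict(spec.submodel_of_species),
        "state_covariates": {k: list(v) for k, v in spec.state_covariates.items()},
        "detection_covariates": {k: list(v) for k, v in spec.detection_covariates.items()},
        "interactions": [[e.source, e.target, e.target_parameter]
                         for e in spec.interactions],
        "selection_enabled": spec.selection_enabled,
        "random_intercepts": spec.random_intercepts,
    }


def spec_from_dict(d: dict) -> ModelSpec:
    """Build a ModelSpec from its declarative form.

    Interaction entries are ``[source, target, target_parameter]``; the
    source quantity (latent N vs z) follows from the source's submodel.
    """
    submodels = dict(d["submodels"])
    interactions = []
    for src, tgt, param in d.get("interactions", []):
        q = LATENT_N if submodels.get(src) == ABUNDANCE_RN else LATENT_Z
        interactions.append(Interaction(src, q, tgt, param))
    return ModelSpec(
        species=list(d["species"]),
        submodel_of_species=submodels,
        state_covariates={k: list(v) for k, v in d.get("state_covariates", {}).items()},
        detection_covariates={k: list(v) for k, v in d.get("detection_covariates", {}).items()},
        interactions=interactions,
        selection_enabled=bool(d.get("selection_enabled", True)),
        random_intercepts=bool(d.get("random_intercepts", True)),
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def read_design(path) -> SurveyDesign:
    """Read a survey-design table (site, array, active_1..active_J)."""
    df = pd.read_csv(path)
    required = {"site", "array"}
    if not required <= set(df.columns):
        raise DataError(f"design file must have columns {sorted(required)}")
    occ_cols = [c for c in df.columns if c.startswith("active_")]
    if not occ_cols:
        raise DataError("design file has no active_<j> occasion columns")
    occ_cols.sort(key=lambda c: int(c.split("_")[1]))
    if df["site"].duplicated().any():
        raise DataError("duplicate site rows in design file")
    site_labels = tuple(df["site"].tolist())
    array_names = tuple(pd.unique(df["array"]))
    a_index = {a: i for i, a in enumerate(array_names)}
    array_of_site = np.array([a_index[a] for a in df["array"]], dtype=np.intp)
    active = df[occ_cols].to_numpy(dtype=float)
    if not np.isin(active, [0.0, 1.0]).all():
        raise DataError("active flags must be 0/1")
    return SurveyDesign(site_labels=site_labels, array_of_site=array_of_site,
                        array_names=array_names, active=active.astype(bool))


def read_detection_data(path, design_path) -> DetectionData:
    """Read long-format detection histories against a survey design.

    Active cells absent from the file default to 0 (surveyed, nothing seen).
    Cells the design marks inactive are missing regardless of file content;
    a detection recorded in an inactive cell is dropped with a warning.

    Raises
    ------
    DataError
        On unknown site/occasion references, non-binary ``detected`` values,
        or duplicate (species, site, occasion) rows.
    """
    design = read_design(design_path)
    df = pd.read_csv(path)
    required = {"species", "site", "occasion", "detected"}
    if not required <= set(df.columns):
        raise DataError(f"detection file must have columns {sorted(required)}")
    if not np.isin(df["detected"].to_numpy(), [0, 1]).all():
        raise DataError("detected column must be 0/1")
    if df.duplicated(["species", "site", "occasion"]).any():
        dupes = df[df.duplicated(["species", "site", "occasion"], keep=False)]
        raise DataError(f"duplicate (species, site, occasion) rows:\n{dupes.head()}")
    site_idx = {lab: i for i, lab in enumerate(design.site_labels)}
    unknown = set(df["site"]) - set(site_idx)
    if unknown:
        raise DataError(f"unknown sites in detection file: {sorted(unknown)}")
    occ = df["occasion"].to_numpy()
    if occ.min() < 1 or occ.max() > design.n_occasions:
        raise DataError(f"occasion out of range 1..{design.n_occasions}")
    histories = {}
    for sp, block in df.groupby("species", sort=False):
        h = np.zeros((design.n_sites, design.n_occasions), dtype=np.int8)
        rows = np.array([site_idx[s] for s in block["site"]])
        cols = block["occasion"].to_numpy() - 1
        h[rows, cols] = block["detected"].to_numpy()
        clobbered = (h == 1) & ~design.active
        if clobbered.any():
            logger.warning("species %r: %d detections at inactive cells dropped",
                           sp, int(clobbered.sum()))
        h[~design.active] = MISSING
        histories[sp] = h
    return DetectionData(histories=histories, design=design)


def write_design(design: SurveyDesign, path) -> None:
    cols = {"site": list(design.site_labels),
            "array": [design.array_names[a] for a in design.array_of_site]}
    for j in range(design.n_occasions):
        cols[f"active_{j + 1}"] = design.active[:, j].astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)


def write_detection_data(data: DetectionData, path) -> None:
    """Write histories in the long format :func:`read_detection_data` reads.

    Every active cell is written explicitly (including zeros) so the
    round-trip is bit-exact on the 0/1/missing pattern.
    """
    rows = []
    design = data.design
    for sp, h in data.histories.items():
        for i in range(design.n_sites):
            for j in range(design.n_occasions):
                if design.active[i, j]:
                    rows.append((sp, design.site_labels[i], j + 1, int(h[i, j])))
    pd.DataFrame(rows, columns=["species", "site", "occasion", "detected"]).to_csv(
        path, index=False)


def read_covariates(path, binary: list | None = None) -> CovariateTable:
    """Read per-site covariates; columns whose values are all 0/1 are binary.

    Pass ``binary`` to name the binary columns explicitly (a continuous
    covariate can in principle take only the values 0 and 1).
    """
    df = pd.read_csv(path)
    if "site" in df.columns:
        df = df.drop(columns=["site"])
    cont, binr = {}, {}
    for c in df.columns:
        x = df[c].to_numpy(dtype=float)
        is_binary = c in binary if binary is not None else np.isin(x, [0.0, 1.0]).all()
        (binr if is_binary else cont)[c] = x
    return CovariateTable(continuous=cont, binary=binr)


def write_covariates(covs: CovariateTable, path, site_labels=None) -> None:
    cols = {}
    if site_labels is not None:
        cols["site"] = list(site_labels)
    for name in covs.continuous:
        cols[name] = covs.continuous[name]
    for name in covs.binary:
        cols[name] = covs.binary[name].astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)
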