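"""Data model and I/O for predation-trial count tables.

Two experimental designs are supported:

* ``prey_choice`` — vessels stocked with a fixed community of potential prey
  (six species, 6-30 individuals each), with or without the focal consumer
  (*Sigara striata*); one row per vessel x prey species.
* ``predation`` — vessels stocked with 10 *Sigara* adults and a single
  predator individual (or no predator, for controls); one row per vessel.

Tables are plain CSV (comma-separated, UTF-8, ``.`` decimal, one header row,
enums as lowercase strings).  Packaged fixtures carry the prey community and
the 13-predator trait list of the original study.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

FORAGING_MODES = ("ambush", "searching")
FEEDING_MODES = ("chewing", "suctorial")
MICROHABITATS = ("benthic", "pelagic")
SCHEMAS = ("prey_choice", "predation")

CONTROL_LABEL = "control"

TRIAL_COLUMNS = ("experiment", "vessel_id", "group_label",
                 "treatment", "n_initial", "n_dead")

#: Column-name adapter for externally supplied raw-data files: maps common
#: alternative headers onto the canonical ``TRIAL_COLUMNS``.  Pass it (or a
#: user-extended copy) to :func:`read_trials` via ``column_map``.
SUPPLEMENTARY_COLUMN_MAP = {
    "predator": "group_label",
    "prey": "group_label",
    "species": "group_label",
    "vessel": "vessel_id",
    "replicate": "vessel_id",
    "sigara_present": "treatment",
    "n_start": "n_initial",
    "n_killed": "n_dead",
    "dead": "n_dead",
}


class TrialDataError(ValueError):
    """Base class for trial-table validation failures."""


class MissingColumnError(TrialDataError):
    """A required column is absent from the input file."""


class CountValueError(TrialDataError):
    """A count field is not a non-negative integer."""


class CountBoundsError(TrialDataError):
    """n_dead exceeds n_initial (or n_initial is not positive)."""


class EnumLevelError(TrialDataError):
    """A categorical field holds a value outside its two allowed levels."""


class DuplicateVesselError(TrialDataError):
    """Vessel identifiers are not unique within the experiment."""


class UnknownGroupError(TrialDataError):
    """A non-control group label has no matching predator-trait entry."""


@dataclass(frozen=True)
class PreySpecies:
    """A potential prey species and its measured traits."""

    name: str
    initial_count_per_vessel: int
    mean_length_mm: float
    mean_mass_mg: float
    microhabitat: str
    n_measured: int | None = None  # individuals measured/weighed, not replicates
    sd_length_mm: float | None = None
    sd_mass_mg: float | None = None

    def __post_init__(self) -> None:
        if self.initial_count_per_vessel <= 0:
            raise CountBoundsError(f"{self.name}: non-positive initial count")
        if self.mean_length_mm <= 0 or self.mean_mass_mg <= 0:
            raise TrialDataError(f"{self.name}: non-positive size measurement")
        if self.microhabitat not in MICROHABITATS:
            raise EnumLevelError(f"{self.name}: microhabitat {self.microhabitat!r}")


@dataclass(frozen=True)
class PredatorTraits:
    """A predator (species + life stage) and the traits entering the model."""

    name: str
    n_replicates: int
    mass_mg: float
    foraging_mode: str
    feeding_mode: str
    microhabitat: str
    mean_length_mm: float | None = None
    sd_length_mm: float | None = None
    sd_mass_mg: float | None = None

    def __post_init__(self) -> None:
        if self.n_replicates <= 0:
            raise CountBoundsError(f"{self.name}: non-positive replicate count")
        if self.mass_mg <= 0:
            raise TrialDataError(f"{self.name}: non-positive body mass")
        if self.foraging_mode not in FORAGING_MODES:
            raise EnumLevelError(f"{self.name}: foraging_mode {self.foraging_mode!r}")
        if self.feeding_mode not in FEEDING_MODES:
            raise EnumLevelError(f"{self.name}: feeding_mode {self.feeding_mode!r}")
        if self.microhabitat not in MICROHABITATS:
            raise EnumLevelError(f"{self.name}: microhabitat {self.microhabitat!r}")


@dataclass(frozen=True)
class TrialObservation:
    """One binomial trial: ``n_dead`` of ``n_initial`` individuals died.

    ``group_label`` is the prey species (prey-choice design), the predator
    identity (predation design), or ``"control"``.  ``treatment`` marks
    presence of the focal consumer and must be 0 for controls.
    """

    experiment: str
    vessel_id: str
    group_label: str
    treatment: int
    n_initial: int
    n_dead: int

    def __post_init__(self) -> None:
        if self.experiment not in SCHEMAS:
            raise EnumLevelError(f"unknown experiment schema {self.experiment!r}")
        if self.treatment not in (0, 1):
            raise EnumLevelError(
                f"vessel {self.vessel_id}: treatment must be 0/1, got {self.treatment!r}")
        if self.n_initial <= 0:
            raise CountBoundsError(f"vessel {self.vessel_id}: n_initial must be positive")
        if not 0 <= self.n_dead <= self.n_initial:
            raise CountBoundsError(
                f"vessel {self.vessel_id} ({self.group_label}): "
                f"n_dead={self.n_dead} outside [0, n_initial={self.n_initial}]")
        if self.group_label == CONTROL_LABEL and self.treatment != 0:
            raise EnumLevelError(
                f"vessel {self.vessel_id}: control rows must have treatment=0")


@dataclass
class ExperimentTable:
    """An ordered collection of trials, optionally joined to predator traits."""

    observations: list[TrialObservation]
    traits: dict[str, PredatorTraits] | None = None
    schema: str = "predation"

    def __post_init__(self) -> None:
        if self.schema not in SCHEMAS:
            raise EnumLevelError(f"unknown schema {self.schema!r}")
        seen: set[tuple[str, str]] = set()
        for obs in self.observations:
            # prey-choice vessels hold one row per prey species, so uniqueness
            # is on (vessel, group); predation vessels hold a single row
            key = (obs.vessel_id, obs.group_label if self.schema == "prey_choice" else "")
            if key in seen:
                raise DuplicateVesselError(
                    f"duplicate vessel {obs.vessel_id!r}"
                    + (f" for group {obs.group_label!r}" if self.schema == "prey_choice" else ""))
            seen.add(key)
        if self.traits is not None:
            for obs in self.observations:
                if obs.group_label != CONTROL_LABEL and obs.group_label not in self.traits:
                    raise UnknownGroupError(
                        f"group {obs.group_label!r} has no predator-trait entry")

    def __len__(self) -> int:
        return len(self.observations)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(o) for o in self.observations],
                            columns=list(TRIAL_COLUMNS))

    def non_control(self) -> "ExperimentTable":
        keep = [o for o in self.observations if o.group_label != CONTROL_LABEL]
        return ExperimentTable(keep, traits=self.traits, schema=self.schema)

    def group_labels(self) -> list[str]:
        """Distinct non-control group labels in first-appearance order."""
        out: list[str] = []
        for o in self.observations:
            if o.group_label != CONTROL_LABEL and o.group_label not in out:
                out.append(o.group_label)
        return out


def _coerce_int(value, column: str, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise CountValueError(f"row {row}: {column}={value!r} is not an integer") from None
    if not f.is_integer():
        raise CountValueError(f"row {row}: {column}={value!r} is not an integer")
    return int(f)


def table_from_frame(frame: pd.DataFrame, schema: str,
                     traits: dict[str, PredatorTraits] | None = None) -> ExperimentTable:
    """Validate a raw dataframe row by row and build an :class:`ExperimentTable`."""
    if schema not in SCHEMAS:
        raise EnumLevelError(f"unknown schema {schema!r}")
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns and c != "experiment"]
    if missing:
        raise MissingColumnError(f"missing column(s): {', '.join(missing)}")
    observations = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        rec = dict(zip(frame.columns, row))
        try:
            observations.append(TrialObservation(
                experiment=str(rec.get("experiment", schema)),
                vessel_id=str(rec["vessel_id"]),
                group_label=str(rec["group_label"]).strip(),
                treatment=_coerce_int(rec["treatment"], "treatment", idx),
                n_initial=_coerce_int(rec["n_initial"], "n_initial", idx),
                n_dead=_coerce_int(rec["n_dead"], "n_dead", idx),
            ))
        except TrialDataError as err:
            raise type(err)(f"row {idx}: {err}") from None
    return ExperimentTable(observations, traits=traits, schema=schema)


def read_trials(path, schema: str, traits: dict[str, PredatorTraits] | None = None,
                column_map: dict[str, str] | None = None) -> ExperimentTable:
    """Read a trial table from CSV, validating every row.

    ``column_map`` renames foreign headers onto the canonical ones before
    validation (see :data:`SUPPLEMENTARY_COLUMN_MAP`), so externally supplied
    raw-data files can be ingested without editing them.
    """
    frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    if column_map:
        frame = frame.rename(columns=column_map)
    if "experiment" not in frame.columns:
        frame = frame.assign(experiment=schema)
    return table_from_frame(frame, schema, traits=traits)


def write_trials(table: ExperimentTable, path) -> None:
    """Write a table in the canonical CSV dialect (round-trips losslessly)."""
    table.to_frame().to_csv(path, index=False)


def _data_file(name: str):
    return resources.files("predmort").joinpath("data", name)


def packaged_fixtures() -> tuple[list[PreySpecies], list[PredatorTraits]]:
    """The study's prey community (6 species) and predator list (13 entries)."""
    prey_df = pd.read_csv(_data_file("prey_species.csv"))
    pred_df = pd.read_csv(_data_file("predator_traits.csv"))
    prey = [PreySpecies(
        name=r.name, n_measured=int(r.n_measured),
        mean_length_mm=float(r.mean_length_mm), sd_length_mm=float(r.sd_length_mm),
        mean_mass_mg=float(r.mean_mass_mg), sd_mass_mg=float(r.sd_mass_mg),
        microhabitat=r.microhabitat,
        initial_count_per_vessel=int(r.initial_count_per_vessel),
    ) for r in prey_df.itertuples(index=False)]
    predators = [PredatorTraits(
        name=r.name, n_replicates=int(r.n_replicates),
        mean_length_mm=float(r.mean_length_mm), sd_length_mm=float(r.sd_length_mm),
        mass_mg=float(r.mass_mg), sd_mass_mg=float(r.sd_mass_mg),
        foraging_mode=r.foraging_mode, feeding_mode=r.feeding_mode,
        microhabitat=r.microhabitat,
    ) for r in pred_df.itertuples(index=False)]
    return prey, predators


def predator_trait_map(predators: list[PredatorTraits] | None = None) -> dict[str, PredatorTraits]:
    if predators is None:
        predators = packaged_fixtures()[1]
    return {p.name: p for p in predators}
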