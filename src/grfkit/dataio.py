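"""Reading, writing and rescaling of gene-expression time-series data.

The exchange format is a TSV matrix with genes as rows and sampling times
(minutes) as columns; a companion TSV lists allowed regulator->target
interactions.  All concentrations are in arbitrary units: the downstream
regulation functions respond to ratios of protein level to fitted binding
constants, so only relative dynamics matter.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Kind",
    "TimeGrid",
    "GeneTimeSeries",
    "TimeSeriesSet",
    "InteractionMatrix",
    "FormatError",
    "DegenerateInputError",
    "default_grid",
    "read_timeseries",
    "write_timeseries",
    "read_interactions",
    "rescale_to_reference",
]

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


class DegenerateInputError(ValueError):
    """Raised when an input series is degenerate for the requested operation."""


class Kind(str, enum.Enum):
    """What a time series measures."""

    mrna_level = "mrna_level"
    synthesis_rate = "synthesis_rate"
    protein_proxy = "protein_proxy"


@dataclass(frozen=True)
class TimeGrid:
    """Strictly increasing sampling times in minutes."""

    times: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise ValueError("a time grid needs at least two points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("sampling times must be strictly increasing")
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.times.size

    def __eq__(self, other) -> bool:
        return isinstance(other, TimeGrid) and np.array_equal(self.times, other.times)

    def __hash__(self):
        return hash(self.times.tobytes())

    @property
    def span(self) -> float:
        """Total duration covered by the grid, minutes."""
        return float(self.times[-1] - self.times[0])


def default_grid() -> TimeGrid:
    """The standard measurement grid: 42 points at 0, 5, ..., 205 min."""
    return TimeGrid(np.arange(0.0, 210.0, 5.0))


@dataclass(frozen=True)
class GeneTimeSeries:
    """One gene's trace (mRNA level, synthesis rate or protein proxy) on a grid."""

    gene: str
    kind: Kind
    values: np.ndarray
    grid: TimeGrid
    replicate: str = "1"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.grid),):
            raise ValueError(
                f"{self.gene}: {v.size} values for a {len(self.grid)}-point grid"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{self.gene}: non-finite values")
        if self.kind in (Kind.mrna_level, Kind.synthesis_rate) and np.any(v < 0):
            raise ValueError(f"{self.gene}: negative {self.kind.value} values")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "kind", Kind(self.kind))

    def with_values(self, values: np.ndarray, kind: Kind | None = None) -> "GeneTimeSeries":
        return GeneTimeSeries(self.gene, kind or self.kind, np.asarray(values, float),
                              self.grid, self.replicate)


class TimeSeriesSet:
    """Collection of traces keyed by (gene, kind, replicate), one grid per replicate."""

    def __init__(self, entries: list[GeneTimeSeries] | None = None):
        self._entries: dict[tuple[str, Kind, str], GeneTimeSeries] = {}
        self._grids: dict[str, TimeGrid] = {}
        for e in entries or []:
            self.add(e)

    def add(self, series: GeneTimeSeries) -> None:
        grid = self._grids.get(series.replicate)
        if grid is not None and grid != series.grid:
            raise ValueError(
                f"replicate {series.replicate!r} already uses a different time grid"
            )
        self._grids[series.replicate] = series.grid
        self._entries[(series.gene, series.kind, series.replicate)] = series

    def get(self, gene: str, kind: Kind, replicate: str = "1") -> GeneTimeSeries:
        return self._entries[(gene, Kind(kind), replicate)]

    def __contains__(self, key) -> bool:
        gene, kind, rep = key
        return (gene, Kind(kind), rep) in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def genes(self, kind: Kind | None = None, replicate: str | None = None) -> list[str]:
        out = []
        for (g, k, r), _ in self._entries.items():
            if kind is not None and k != Kind(kind):
                continue
            if replicate is not None and r != replicate:
                continue
            if g not in out:
                out.append(g)
        return out

    def replicates(self) -> list[str]:
        return sorted(self._grids)


@dataclass
class InteractionMatrix:
    """Directed allowed-regulation relation: (regulator, target) pairs."""

    nodes: list[str]
    allowed: set[tuple[str, str]]
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def regulators_of(self, target: str) -> list[str]:
        return sorted(r for (r, t) in self.allowed if t == target)

    def targets_of(self, regulator: str) -> list[str]:
        return sorted(t for (r, t) in self.allowed if r == regulator)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in self.allowed


def read_timeseries(path, kind: Kind, replicate: str = "1") -> TimeSeriesSet:
    """Read a gene x time TSV matrix into a :class:`TimeSeriesSet`.

    The header row carries the sampling times in minutes; the first column
    is the gene identifier.  The grid is defined by the file, not hard-coded.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: unreadable TSV ({exc})") from exc
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need at least two time columns")
    try:
        times = np.array([float(c) for c in df.columns])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric time in header: {exc}") from exc
    if not np.all(np.diff(times) > 0):
        raise FormatError(f"{path}: header times are not strictly increasing")
    grid = TimeGrid(times)
    out = TimeSeriesSet()
    for gene, row in df.iterrows():
        # cell-wise float() parsing: exact round-trip, unlike the fast
        # pandas string-to-float path
        vals = np.empty(row.size)
        for j, cell in enumerate(row.to_numpy()):
            try:
                vals[j] = float(cell)
            except (TypeError, ValueError):
                vals[j] = np.nan
        bad = np.nonzero(~np.isfinite(vals))[0]
        if bad.size:
            raise FormatError(
                f"{path}: non-numeric value for gene {gene!r} at t={times[bad[0]]:g} min"
            )
        out.add(GeneTimeSeries(str(gene), kind, vals, grid, replicate))
    return out


def write_timeseries(tss: TimeSeriesSet, path, kind: Kind, replicate: str = "1") -> None:
    """Write one kind/replicate slice of a set to a TSV matrix (full precision)."""
    genes = tss.genes(kind=kind, replicate=replicate)
    if not genes:
        raise ValueError("nothing to write for that kind/replicate")
    grid = tss.get(genes[0], kind, replicate).grid
    df = pd.DataFrame(
        {g: tss.get(g, kind, replicate).values for g in genes},
        index=grid.times,
    ).T
    df.columns = [repr(float(t)) for t in grid.times]
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_interactions(path) -> InteractionMatrix:
    """Read a regulator/target TSV into a deduplicated directed relation."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise FormatError(f"{path}: empty interaction table")
    cols = {c.lower(): c for c in df.columns}
    if "regulator" not in cols or "target" not in cols:
        raise FormatError(f"{path}: need 'regulator' and 'target' columns")
    allowed: set[tuple[str, str]] = set()
    provenance: dict[tuple[str, str], str] = {}
    nodes: list[str] = []
    for _, row in df.iterrows():
        pair = (str(row[cols["regulator"]]).strip(), str(row[cols["target"]]).strip())
        if pair in allowed:
            warnings.warn(f"duplicate interaction {pair} collapsed", stacklevel=2)
        allowed.add(pair)
        if "reference" in cols and pd.notna(row[cols["reference"]]):
            provenance[pair] = str(row[cols["reference"]])
        for g in pair:
            if g not in nodes:
                nodes.append(g)
    return InteractionMatrix(nodes=nodes, allowed=allowed, provenance=provenance)


def write_interactions(mat: InteractionMatrix, path) -> None:
    rows = [
        {"regulator": r, "target": t, "reference": mat.provenance.get((r, t), "")}
        for (r, t) in sorted(mat.allowed)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def rescale_to_reference(test: GeneTimeSeries, reference: GeneTimeSeries) -> GeneTimeSeries:
    """Affinely map ``test`` so its min/max match those of ``reference``.

    Used to compare external (differently normalised) expression data against
    the calibration dataset: y = a + b*test with
    b = (max ref - min ref) / (max test - min test) and a = min ref - b*min test.
    Inputs must be on linear (not log) scale.
    """
    tv, rv = test.values, reference.values
    if np.ptp(tv) == 0:
        raise DegenerateInputError(f"{test.gene}: constant test series cannot be rescaled")
    if np.ptp(rv) == 0:
        raise DegenerateInputError(f"{reference.gene}: constant reference series")
    b = np.ptp(rv) / np.ptp(tv)
    a = rv.min() - b * tv.min()
    return test.with_values(a + b * tv)


# --- JSON result serialization -------------------------------------------------

def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, enum.Enum):
        return obj.value
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def dump_json(payload: dict, path) -> None:
    """Serialize a result dict with an explicit schema version."""
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_jsonify)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
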