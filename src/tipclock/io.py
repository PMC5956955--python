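"""Readers and writers for the on-disk formats, plus run configuration.

Formats: Newick trees (dendropy), FASTA alignments, TSV tip-date tables
(header ``name\\tage_years_bp``), YAML run configuration.  All writes are
atomic (temp file + rename) and each output gets a JSON sidecar recording
the configuration and seed that produced it.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import dendropy
import yaml

from .seqsim import Alignment
from .treesim import ClusteringLevel, ScenarioConfig, TipDates

__all__ = [
    "RunConfig",
    "read_newick",
    "write_newick",
    "read_dates",
    "write_dates",
    "read_fasta",
    "write_fasta",
    "write_lsd_dates",
    "atomic_write_text",
]

DATE_HEADER = "name\tage_years_bp"


class NewickParseError(ValueError):
    """Malformed Newick input."""


@dataclass
class RunConfig:
    """Scenario parameters plus estimator/diagnostic options for a run."""

    mean_rate: float = 1e-7
    variance_fraction: float = 0.01
    clustering: str = "none"
    n_tips: int = 100
    frac_modern: float = 0.5
    max_ancient_age: float = 50_000.0
    root_age: float = 500_000.0
    seq_length: int = 15_000
    effective_size: float = 250_000.0
    n_replicates: int = 100
    seed: int = 0
    methods: tuple[str, ...] = ("rtt", "lsd")
    n_boot: int = 100
    level: float = 0.95
    lsd_variance_offset_c: float = 10.0
    n_perm_clustering: int = 1000
    n_drt_reps: int = 20
    out_dir: str = "results"
    log_level: str = "INFO"

    def scenario(self) -> ScenarioConfig:
        return ScenarioConfig(
            mean_rate=self.mean_rate,
            variance_fraction=self.variance_fraction,
            clustering=ClusteringLevel(self.clustering),
            n_tips=self.n_tips,
            frac_modern=self.frac_modern,
            max_ancient_age=self.max_ancient_age,
            root_age=self.root_age,
            seq_length=self.seq_length,
            effective_size=self.effective_size,
            n_replicates=self.n_replicates,
            seed=self.seed,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        if "methods" in data:
            data["methods"] = tuple(data["methods"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["methods"] = list(data["methods"])
        atomic_write_text(path, yaml.safe_dump(data, sort_keys=True))


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_provenance(path: str | Path, config: dict | None, seed: int | None) -> None:
    """JSON sidecar recording what produced an output file."""
    side = Path(str(path) + ".provenance.json")
    atomic_write_text(
        side, json.dumps({"config": config, "seed": seed}, indent=2, default=str) + "\n"
    )


def read_newick(
    path: str | Path,
    require_binary: bool = False,
    resolve_polytomies: bool = False,
) -> dendropy.Tree:
    """Parse a Newick tree with branch lengths; optional binarity handling.

    ``require_binary`` rejects polytomies (simulator time-trees are
    binary); ``resolve_polytomies`` breaks them with zero-length edges.
    """
    text = Path(path).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True,
        )
    except Exception as exc:
        offset = getattr(exc, "column", None)
        raise NewickParseError(
            f"malformed Newick in {path}"
            + (f" (near character {offset})" if offset is not None else "")
            + f": {exc}"
        ) from exc
    polytomies = [
        n for n in tree.preorder_internal_node_iter() if len(n.child_nodes()) > 2
    ]
    # an unrooted basal trichotomy is conventional, not a polytomy proper
    real = [n for n in polytomies if n.parent_node is not None]
    if require_binary and (real or (polytomies and len(tree.seed_node.child_nodes()) > 3)):
        raise ValueError(f"tree in {path} contains polytomies; a binary tree is required")
    if resolve_polytomies and polytomies:
        tree.resolve_polytomies()
        for edge in tree.preorder_edge_iter():
            if edge.length is None and edge.head_node.parent_node is not None:
                edge.length = 0.0
    return tree


def write_newick(
    path: str | Path,
    tree: dendropy.Tree,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    text = tree.as_string(
        schema="newick", suppress_rooting=True,
        real_value_format_specifier=".12g",
    ).strip() + "\n"
    atomic_write_text(path, text)
    write_provenance(path, config, seed)


def read_dates(path: str | Path) -> TipDates:
    """Read a tip-date TSV (``name\\tage_years_bp``); validates ages and names."""
    lines = [
        ln for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    if not lines or lines[0].strip() != DATE_HEADER:
        raise ValueError(f"expected header {DATE_HEADER!r} in {path}")
    entries: dict[str, float] = {}
    for ln in lines[1:]:
        name, age_s = ln.split("\t")
        age = float(age_s)
        if age < 0:
            raise ValueError(f"negative age for tip {name!r}")
        if name in entries:
            raise ValueError(f"duplicate tip name {name!r}")
        entries[name] = age
    return TipDates(entries)


def write_dates(
    path: str | Path,
    dates: TipDates,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    rows = [DATE_HEADER]
    rows += [f"{name}\t{age:.12g}" for name, age in dates.entries.items()]
    atomic_write_text(path, "\n".join(rows) + "\n")
    write_provenance(path, config, seed)


def write_lsd_dates(path: str | Path, dates: TipDates) -> None:
    """Export shim for the LSD date-file dialect (count line, then name age)."""
    rows = [str(len(dates.entries))]
    rows += [f"{name} {age:.12g}" for name, age in dates.entries.items()]
    atomic_write_text(path, "\n".join(rows) + "\n")


def read_fasta(path: str | Path) -> Alignment:
    return Alignment.from_fasta(Path(path).read_text())


def write_fasta(
    path: str | Path,
    alignment: Alignment,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    atomic_write_text(path, alignment.to_fasta())
    write_provenance(path, config, seed)
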