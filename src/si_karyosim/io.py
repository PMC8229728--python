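"""File formats, fixtures and reproducibility sidecars.

Tables are tab-delimited UTF-8 with Unix newlines; configurations are JSON
or TOML interchangeably; trajectories are CSV.  Every CLI run writes a JSON
sidecar next to its output recording the resolved configuration, the seed
and the package version, so that any result can be regenerated exactly.
"""

from __future__ import annotations

import csv
import json
import tomllib
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from . import __version__
from .dynamics import RWParams, Trajectory
from .genetics import (
    CompatibilityResult,
    GeneticsError,
    Haplotype,
    Locus,
    Mycelium,
)

__all__ = [
    "read_loci",
    "write_loci",
    "read_genotypes",
    "write_compat_matrix",
    "read_params",
    "write_params",
    "trajectory_to_csv",
    "write_sidecar",
    "generate_fixtures",
]


# ---------------------------------------------------------------------------
# Loci
# ---------------------------------------------------------------------------


def _loci_from_records(records: Iterable[dict], source: str) -> list[Locus]:
    out = []
    for rec in records:
        try:
            out.append(Locus(str(rec["id"]), tuple(rec["alleles"]),
                             tuple(float(f) for f in rec["frequencies"])))
        except GeneticsError as e:
            raise GeneticsError(f"{source}: {e}") from None
        except (KeyError, TypeError) as e:
            raise GeneticsError(f"{source}: malformed locus record ({e})") from None
    if not out:
        raise GeneticsError(f"{source}: no loci defined")
    return out


def read_loci(path: str | Path) -> list[Locus]:
    """Read locus definitions from JSON, TOML or TSV.

    JSON/TOML: ``{"loci": [{"id", "alleles", "frequencies"}, ...]}`` (JSON
    also accepts a bare list).  TSV: columns ``locus, allele, frequency``,
    one row per allele, alleles grouped by locus in file order.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".json":
        data = json.loads(path.read_text())
        records = data["loci"] if isinstance(data, dict) else data
        return _loci_from_records(records, str(path))
    if suffix == ".toml":
        data = tomllib.loads(path.read_text())
        return _loci_from_records(data["loci"], str(path))
    if suffix in (".tsv", ".txt"):
        groups: dict[str, list[tuple[str, float]]] = {}
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                groups.setdefault(row["locus"], []).append(
                    (row["allele"], float(row["frequency"]))
                )
        records = [
            {"id": lid, "alleles": [a for a, _ in rows],
             "frequencies": [f for _, f in rows]}
            for lid, rows in groups.items()
        ]
        return _loci_from_records(records, str(path))
    raise GeneticsError(f"unsupported locus file format: {path}")


def write_loci(loci: Sequence[Locus], path: str | Path) -> None:
    """Write loci as JSON; ``read_loci`` round-trips to equal loci."""
    payload = {
        "loci": [
            {"id": L.id, "alleles": list(L.alleles),
             "frequencies": list(L.frequencies)}
            for L in loci
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Genotype tables
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, loci: Sequence[Locus]) -> dict[str, Mycelium]:
    """Read isolates from a TSV with columns
    ``isolate_id, locus, nucleus_index, allele`` (nucleus_index 1-3)."""
    per_isolate: dict[str, dict[int, dict[str, str]]] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            nuc = int(row["nucleus_index"])
            per_isolate.setdefault(row["isolate_id"], {}).setdefault(nuc, {})[
                row["locus"]
            ] = row["allele"]
    out = {}
    for iso, nuclei in per_isolate.items():
        haps = tuple(
            Haplotype.from_mapping(nuclei[i]) for i in sorted(nuclei)
        )
        out[iso] = Mycelium(haps)
    if not out:
        raise GeneticsError(f"{path}: no genotypes found")
    return out


# ---------------------------------------------------------------------------
# Compatibility matrices
# ---------------------------------------------------------------------------


def write_compat_matrix(
    result: CompatibilityResult, path: str | Path, style: str = "C"
) -> None:
    """Write a labeled compatibility matrix as TSV.

    ``style="C"`` renders compatible cells as the letter ``C`` and
    incompatible cells as empty, mirroring the published table layout;
    ``style="binary"`` emits 0/1.
    """
    if result.matrix is None:
        raise GeneticsError("result carries no matrix (analytic/MC route)")
    if style not in ("C", "binary"):
        raise GeneticsError(f"unknown matrix style {style!r}")
    rows = []
    rows.append("\t".join([""] + list(result.labels)))
    for lab, row in zip(result.labels, result.matrix):
        if style == "C":
            cells = ["C" if c else "" for c in row]
        else:
            cells = ["1" if c else "0" for c in row]
        rows.append("\t".join([lab] + cells))
    Path(path).write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# Kinetic parameters and trajectories
# ---------------------------------------------------------------------------


def read_params(path: str | Path) -> RWParams:
    """Read reader/writer kinetic parameters from JSON or TOML."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    return RWParams.from_dict(data)


def write_params(params: RWParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2, sort_keys=True) + "\n")


def trajectory_to_csv(traj: Trajectory, path: str | Path, every: int = 1) -> None:
    """Write a trajectory as CSV (t, R_<allele>..., U_<allele>..., S, alive);
    death metadata goes in a JSON sidecar next to the file."""
    path = Path(path)
    header = (
        ["t"]
        + [f"R_{a}" for a in traj.alleles]
        + [f"U_{a}" for a in traj.alleles]
        + ["S", "alive"]
    )
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for i in range(0, len(traj.times), every):
            t = traj.times[i]
            dead = traj.death_time is not None and t >= traj.death_time
            writer.writerow(
                [f"{t:.6g}"]
                + [f"{x:.10g}" for x in traj.R[i]]
                + [f"{x:.10g}" for x in traj.U[i]]
                + [f"{traj.S[i]:.10g}", int(not dead)]
            )
    meta = {
        "death_time": traj.death_time,
        "peak_signal": traj.peak_signal,
        "peak_time": traj.peak_time,
        "theta": traj.theta,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def write_sidecar(out_path: str | Path, config: dict) -> Path:
    """Write the resolved run configuration next to an output file."""
    out_path = Path(out_path)
    sidecar = out_path.with_suffix(out_path.suffix + ".meta.json")
    payload = dict(config)
    payload["package_version"] = __version__
    sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return sidecar


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------


def generate_fixtures(kind: str, outdir: str | Path, seed: int = 0) -> list[Path]:
    """Emit deterministic synthetic input files.

    kinds:
      - ``loci``: the canonical biallelic and triallelic uniform loci plus a
        seeded random two-locus system (k in 2..4);
      - ``population``: a genotype TSV of heterokaryon isolates with planted
        clonal replicates;
      - ``scenario``: the four canonical colony-interface pairings
        (homokaryon mating, Buller mating, distinct heterokaryons,
        common-nucleus heterokaryons);
      - ``params``: the shipped default kinetic parameters.

    A fixed seed yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written: list[Path] = []

    def emit_json(name: str, payload: dict) -> None:
        p = outdir / name
        p.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        written.append(p)

    if kind == "loci":
        write_loci([Locus.uniform("X", 2)], outdir / "loci_biallelic.json")
        write_loci([Locus.uniform("X", 3)], outdir / "loci_triallelic.json")
        random_loci = []
        for i in range(2):
            k = int(rng.integers(2, 5))
            raw = rng.dirichlet(np.ones(k))
            freqs = np.round(raw, 6)
            freqs[-1] = 1.0 - float(freqs[:-1].sum())
            random_loci.append(
                Locus(f"L{i + 1}", tuple(f"A{j + 1}" for j in range(k)),
                      tuple(float(f) for f in freqs))
            )
        write_loci(random_loci, outdir / "loci_random.json")
        written.extend(
            outdir / n for n in
            ("loci_biallelic.json", "loci_triallelic.json", "loci_random.json")
        )
    elif kind == "population":
        locus = Locus.uniform("X", 3)
        n_isolates, n_clones = 30, 10
        clone_genos = [
            tuple(rng.choice(locus.alleles, size=2)) for _ in range(n_clones)
        ]
        p = outdir / "population.tsv"
        with p.open("w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["isolate_id", "locus", "nucleus_index", "allele"])
            for i in range(n_isolates):
                g = clone_genos[i % n_clones]
                for nuc, allele in enumerate(g, start=1):
                    w.writerow([f"iso{i + 1:03d}", locus.id, nuc, allele])
        written.append(p)
        write_loci([locus], outdir / "population_loci.json")
        written.append(outdir / "population_loci.json")
    elif kind == "scenario":
        base = {
            "mating_compatible": True,
            "migration_rate": 1.0,
            "n_fusion_cells": 100,
            "seed": int(seed),
            "model": "ptm_plus_migration",
        }
        emit_json("scenario_hom_x_hom.json",
                  {**base, "partner1": ["A"], "partner2": ["B"]})
        emit_json("scenario_buller.json",
                  {**base, "partner1": ["A", "B"], "partner2": ["C"]})
        emit_json("scenario_het_x_het.json",
                  {**base, "partner1": ["A", "B"], "partner2": ["C", "D"]})
        emit_json("scenario_common_nucleus.json",
                  {**base, "partner1": ["A", "B"], "partner2": ["A", "C"]})
    elif kind == "params":
        write_params(RWParams(), outdir / "params_default.json")
        written.append(outdir / "params_default.json")
    else:
        raise GeneticsError(f"unknown fixture kind {kind!r}")
    return written
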