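"""Configuration files, output writers/readers, and fixture generation.

Config format: a single TOML file with ``[rd]``, ``[kmc]``, ``[polymer]``
and ``[output]`` tables whose keys mirror the parameter dataclass fields.
Unknown keys are an error (they usually mean a typo'd parameter name).

Outputs are plain text: lattice samples and profiles as TSV, a JSON
metadata sidecar carrying the schema version, full parameter echo and
seed, so that every output directory is reproducible from its sidecar.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np

from .core import RDParams, RunResult
from .errors import ConfigurationError, ParseError
from .kmc import KMCParams
from .state import SPECIES_NAMES, ParticleSystem
from .stats import Profile, ShellDensity

SCHEMA_VERSION = 1

__all__ = [
    "load_config",
    "write_run",
    "read_samples",
    "write_profile_tsv",
    "read_profile_tsv",
    "make_fixtures",
]


def _params_from_table(cls, table: dict, source: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(table) - valid
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in [{source}]: {', '.join(sorted(unknown))}"
        )
    return cls(**table)


def load_config(path) -> dict:
    """Parse a TOML config into parameter objects.

    Returns a dict with any of the keys ``rd`` (:class:`RDParams`), ``kmc``
    (:class:`KMCParams`), ``polymer`` (plain dict) and ``output`` (plain
    dict) that appear in the file.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {"rd", "kmc", "polymer", "output"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(
            f"unknown table(s) in {path}: {', '.join(sorted(unknown))}"
        )
    out: dict = {}
    if "rd" in raw:
        out["rd"] = _params_from_table(RDParams, raw["rd"], "rd")
    if "kmc" in raw:
        out["kmc"] = _params_from_table(KMCParams, raw["kmc"], "kmc")
    if "polymer" in raw:
        allowed = {"walk_type", "n_beads", "contact_cutoff", "n_configs", "path"}
        unknown = set(raw["polymer"]) - allowed
        if unknown:
            raise ConfigurationError(
                f"unknown key(s) in [polymer]: {', '.join(sorted(unknown))}"
            )
        out["polymer"] = dict(raw["polymer"])
    if "output" in raw:
        out["output"] = dict(raw["output"])
    return out


# ---------------------------------------------------------------- writers


def write_profile_tsv(profile: Profile, path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tP_M\n")
        for i, p in zip(profile.sites, profile.p):
            fh.write(f"{int(i)}\t{p:.8g}\n")


def read_profile_tsv(path) -> Profile:
    sites, ps = [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("site\t"):
            raise ParseError("missing 'site\\tP_M' header", path, 1)
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"expected 2 fields, got {len(parts)}", path, ln)
            try:
                sites.append(int(parts[0]))
                ps.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(str(exc), path, ln) from None
    if not sites:
        raise ParseError("profile file has no data rows", path)
    return Profile(np.array(sites), np.array(ps))


def _write_lattice_samples(samples: np.ndarray, sites: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(str(int(i)) for i in sites) + "\n")
        for row in samples:
            fh.write("\t".join(str(int(v)) for v in row) + "\n")


def _write_particles(system: ParticleSystem, path) -> None:
    with open(path, "w") as fh:
        fh.write("species\tx\ty\n")
        for code, (x, y) in zip(system.species, system.positions):
            fh.write(f"{SPECIES_NAMES[int(code)]}\t{x:.8g}\t{y:.8g}\n")


def _write_shells(shell: ShellDensity, path) -> None:
    with open(path, "w") as fh:
        fh.write("r_lo\tr_hi\tcount\tdensity\n")
        for lo, hi, c, d in zip(
            shell.edges[:-1], shell.edges[1:], shell.counts, shell.densities
        ):
            fh.write(f"{lo:.8g}\t{hi:.8g}\t{c:.8g}\t{d:.8g}\n")


def write_run(result: RunResult, outdir) -> Path:
    """Write a full run to a directory: TSV tables + JSON metadata sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_profile_tsv(result.profile, outdir / "profile.tsv")
    _write_lattice_samples(
        result.lattice_samples, result.profile.sites, outdir / "lattice_samples.tsv"
    )
    _write_particles(result.particles, outdir / "particles.tsv")
    _write_shells(result.shell_density, outdir / "shell_density.tsv")
    with open(outdir / "cprox.tsv", "w") as fh:
        fh.write("site\tC_p\n")
        for i, c in zip(result.profile.sites, result.cprox):
            fh.write(f"{int(i)}\t{c:.8g}\n")
    meta = {"schema_version": SCHEMA_VERSION, **result.metadata}
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def read_samples(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a lattice-sample TSV plus its metadata sidecar.

    Returns ``(samples, site_labels, metadata)``.  A missing sidecar or a
    truncated data file is an explicit error.
    """
    path = Path(path)
    if path.is_dir():
        sample_path = path / "lattice_samples.tsv"
        meta_path = path / "metadata.json"
    else:
        sample_path = path
        meta_path = path.parent / "metadata.json"
    if not meta_path.exists():
        raise ParseError(
            "metadata sidecar metadata.json not found next to the samples file; "
            "analysis needs the parameter echo to interpret the samples",
            meta_path,
        )
    with open(meta_path) as fh:
        metadata = json.load(fh)
    with open(sample_path) as fh:
        try:
            sites = np.array([int(v) for v in fh.readline().split("\t")])
        except ValueError:
            raise ParseError("unparseable site header", sample_path, 1) from None
        rows = []
        for ln, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != sites.size:
                raise ParseError(
                    f"expected {sites.size} columns, got {len(parts)} "
                    "(truncated file?)",
                    sample_path,
                    ln,
                )
            try:
                rows.append([int(v) for v in parts])
            except ValueError as exc:
                raise ParseError(str(exc), sample_path, ln) from None
    if not rows:
        raise ParseError("sample file has no data rows", sample_path)
    return np.array(rows, dtype=np.uint8), sites, metadata


def make_fixtures(outdir, seed: int = 7) -> Path:
    """Deterministic small seeded runs for tests and demos."""
    from .core import run_rd_simulation
    from .kmc import gillespie_run

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rd = RDParams(
        n_nucleosomes=21,
        radius=12.0,
        n_enzymes=60,
        n_steps=6000,
        burn_in=2000,
        sample_interval=100,
        seed=seed,
    )
    write_run(run_rd_simulation(rd), outdir / "rd_small")
    kmc_params = KMCParams.from_K(0.9, n_sites=21, n_events=50_000, seed=seed)
    profile, meta = gillespie_run(kmc_params)
    kmc_dir = outdir / "kmc_small"
    kmc_dir.mkdir(parents=True, exist_ok=True)
    write_profile_tsv(profile, kmc_dir / "profile.tsv")
    with open(kmc_dir / "metadata.json", "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, **meta}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
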