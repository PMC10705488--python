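"""Plain-text readers and writers shared by all pipeline stages.

Internal coordinates are 1-based with closed intervals; BED exports use the
standard 0-based half-open convention.  Every writer states the convention
(and, for stochastic products, the seed and config hash) in ``#`` header
lines; every reader tolerates and skips them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import CALL_TO_STR, MISSING, STR_TO_CALL, GenotypeMatrix
from .lohcall import LOHEvent
from .markers import MarkerMap
from .simulate import CloneTruth, CohortTruth, TrueEvent, TrueMutation

__all__ = [
    "config_hash", "load_config",
    "write_marker_map", "read_marker_map",
    "write_genotypes_tsv", "read_genotypes_tsv",
    "write_genotypes_vcf", "read_genotypes_vcf",
    "write_events_bed", "read_events_bed",
    "write_truth_json", "read_truth_json",
]

COORD_HEADER = "# coordinates: 1-based, closed intervals (BED files: 0-based, half-open)"


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def _meta_lines(meta: dict | None) -> list[str]:
    lines = [COORD_HEADER]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return lines


# -- marker maps: TSV of (chrom, pos) + JSON sidecar ------------------------

def write_marker_map(map: MarkerMap, tsv_path: str | Path,
                     meta: dict | None = None) -> None:
    tsv_path = Path(tsv_path)
    with open(tsv_path, "w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write("chrom\tpos\n")
        for chrom in map.chromosome_names:
            for pos in map.positions(chrom):
                fh.write(f"{chrom}\t{pos}\n")
    sidecar = {
        "chromosomes": [[name, length] for name, length in map.chromosomes],
        "centromeres": {k: list(v) for k, v in map.centromeres.items()},
        "effective_length": map.effective_length,
    }
    with open(tsv_path.with_suffix(tsv_path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_marker_map(tsv_path: str | Path) -> MarkerMap:
    tsv_path = Path(tsv_path)
    sidecar_path = tsv_path.with_suffix(tsv_path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"marker map sidecar {sidecar_path} missing")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    tab = pd.read_csv(tsv_path, sep="\t", comment="#")
    markers = {
        chrom: np.asarray(sub["pos"], dtype=np.int64)
        for chrom, sub in tab.groupby("chrom", sort=False)
    }
    return MarkerMap(
        chromosomes=[(n, int(l)) for n, l in sidecar["chromosomes"]],
        centromeres={k: (int(a), int(b)) for k, (a, b) in sidecar["centromeres"].items()},
        markers=markers,
        effective_length=sidecar.get("effective_length"),
    )


# -- genotype matrices ------------------------------------------------------

def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path,
                        meta: dict | None = None) -> None:
    """TSV matrix: rows = markers (chrom, pos), columns = clones.

    Clone metadata rides along in ``##clone`` header lines.
    """
    with open(path, "w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        for clone in gm.clones:
            m = gm.metadata.loc[clone]
            fh.write(
                f"##clone\t{clone}\tfounder_label={m['founder_label']}"
                f"\tfounder_id={m['founder_id']}\tgenerations={m['generations']}\n"
            )
        fh.write("chrom\tpos\t" + "\t".join(gm.clones) + "\n")
        col = 0
        for chrom in gm.map.chromosome_names:
            for pos in gm.map.positions(chrom):
                calls = "\t".join(CALL_TO_STR[int(v)] for v in gm.calls[:, col])
                fh.write(f"{chrom}\t{pos}\t{calls}\n")
                col += 1


def read_genotypes_tsv(path: str | Path, map: MarkerMap) -> GenotypeMatrix:
    meta_rows = []
    header = None
    data_rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##clone"):
                parts = line.split("\t")
                entry = {"clone": parts[1]}
                for kv in parts[2:]:
                    k, _, v = kv.partition("=")
                    entry[k] = v
                meta_rows.append(entry)
            elif line.startswith("#"):
                continue
            elif header is None:
                header = line.split("\t")
            elif line:
                data_rows.append(line.split("\t"))
    if header is None:
        raise ValueError(f"{path}: no header line")
    clones = header[2:]
    if len(set(clones)) != len(clones):
        raise ValueError(f"{path}: duplicate clone ids")
    if len(data_rows) != map.n_markers:
        raise ValueError(
            f"{path}: {len(data_rows)} marker rows but map has {map.n_markers} "
            "(truncated or mismatched file)"
        )
    calls = np.empty((len(clones), map.n_markers), dtype=np.int8)
    expected = [(chrom, int(pos)) for chrom in map.chromosome_names
                for pos in map.positions(chrom)]
    bad_cells = []
    for i, row in enumerate(data_rows):
        if (row[0], int(row[1])) != expected[i]:
            raise ValueError(f"{path}: marker row {i + 1} does not match the map")
        for j, token in enumerate(row[2:]):
            code = STR_TO_CALL.get(token)
            if code is None:
                bad_cells.append((row[0], row[1], clones[j], token))
            else:
                calls[j, i] = code
    if bad_cells:
        shown = ", ".join(f"{c}:{p} clone {cl} -> {t!r}" for c, p, cl, t in bad_cells[:5])
        raise ValueError(f"{path}: {len(bad_cells)} unknown call symbol(s): {shown}")
    metadata = pd.DataFrame(meta_rows)
    if metadata.empty:
        metadata = pd.DataFrame({"clone": clones, "founder_label": "NA",
                                 "founder_id": "NA", "generations": 0})
    metadata["generations"] = metadata["generations"].astype(int)
    metadata = metadata.set_index("clone").loc[clones]
    return GenotypeMatrix(map, calls, clones, metadata)


_GT_FROM_CODE = {0: "0/1", 1: "0/0", 2: "1/1", MISSING: "./."}
_CODE_FROM_GT = {v: k for k, v in _GT_FROM_CODE.items()}


def write_genotypes_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Minimal VCF-style export: GT 0/1=HET, 0/0=HOM_P1, 1/1=HOM_P2, ./.=MISSING.

    Marker alleles are placeholders (parental haplotype tags), since the map
    does not carry nucleotide-level allele information.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lohdrive (GT encodes parental homolog, not nucleotides)\n")
        for chrom, length in gm.map.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.clones) + "\n")
        col = 0
        for chrom in gm.map.chromosome_names:
            for pos in gm.map.positions(chrom):
                gts = "\t".join(_GT_FROM_CODE[int(v)] for v in gm.calls[:, col])
                fh.write(f"{chrom}\t{pos}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")
                col += 1


def read_genotypes_vcf(path: str | Path, map: MarkerMap) -> GenotypeMatrix:
    clones: list[str] | None = None
    rows: list[tuple[str, int, list[int]]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                clones = line.split("\t")[9:]
                continue
            if not line:
                continue
            if clones is None:
                raise ValueError(f"{path}: missing #CHROM header line")
            parts = line.split("\t")
            gts = []
            for token in parts[9:]:
                gt = token.split(":")[0]
                if gt not in _CODE_FROM_GT:
                    raise ValueError(f"{path}: unsupported GT {gt!r} at {parts[0]}:{parts[1]}")
                gts.append(_CODE_FROM_GT[gt])
            rows.append((parts[0], int(parts[1]), gts))
    if clones is None:
        raise ValueError(f"{path}: not a VCF (no #CHROM line)")
    if len(set(clones)) != len(clones):
        raise ValueError(f"{path}: duplicate clone ids")
    if len(rows) != map.n_markers:
        raise ValueError(f"{path}: {len(rows)} records but map has {map.n_markers} markers")
    calls = np.empty((len(clones), map.n_markers), dtype=np.int8)
    for i, (_, _, gts) in enumerate(rows):
        calls[:, i] = gts
    metadata = pd.DataFrame({
        "clone": clones, "founder_label": "NA", "founder_id": "NA", "generations": 0,
    }).set_index("clone")
    return GenotypeMatrix(map, calls, clones, metadata)


# -- LOH events as BED-like TSV ---------------------------------------------

_BED_COLUMNS = ["chrom", "start", "end", "clone", "class", "homolog",
                "breakpoint", "n_markers", "possible_aneuploidy"]


def _fmt(x: float) -> str:
    """Render midpoint coordinates losslessly (integers without '.0')."""
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def write_events_bed(events: list[LOHEvent], path: str | Path,
                     meta: dict | None = None) -> None:
    """BED-like event table: start is 0-based, end exclusive.

    Midpoint-extrapolated boundaries can be half-integer; they are written
    exactly so the 1-based closed internal interval round-trips.
    """
    with open(path, "w") as fh:
        for line in _meta_lines(meta):
            fh.write(line + "\n")
        fh.write("#" + "\t".join(_BED_COLUMNS) + "\n")
        for e in sorted(events, key=lambda e: (e.clone, e.chrom, e.left)):
            fh.write("\t".join([
                e.chrom, _fmt(e.left - 1), _fmt(e.right), e.clone,
                e.kind or "unclassified", e.homolog,
                _fmt(e.breakpoint) if e.breakpoint is not None else ".",
                str(e.n_markers), str(int(e.possible_aneuploidy)),
            ]) + "\n")


def read_events_bed(path: str | Path) -> pd.DataFrame:
    """Read events back into a table with internal 1-based closed coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != len(_BED_COLUMNS):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(_BED_COLUMNS)} columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append({
                    "clone": parts[3], "chrom": parts[0],
                    "left": float(parts[1]) + 1, "right": float(parts[2]),
                    "class": parts[4], "homolog": parts[5],
                    "breakpoint": float(parts[6]) if parts[6] != "." else np.nan,
                    "n_markers": int(parts[7]),
                    "possible_aneuploidy": bool(int(parts[8])),
                })
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: malformed line ({err})") from None
    frame = pd.DataFrame(
        rows, columns=["clone", "chrom", "left", "right", "class", "homolog",
                       "breakpoint", "n_markers", "possible_aneuploidy"]
    )
    if not frame.empty:
        frame["length"] = frame["right"] - frame["left"]
    return frame


def write_events_json(events: list[LOHEvent], path: str | Path) -> None:
    """JSON export of called events (1-based closed coordinates)."""
    payload = [
        {"clone": e.clone, "chrom": e.chrom, "left": e.left, "right": e.right,
         "class": e.kind, "homolog": e.homolog, "breakpoint": e.breakpoint,
         "n_markers": e.n_markers, "possible_aneuploidy": e.possible_aneuploidy}
        for e in sorted(events, key=lambda e: (e.clone, e.chrom, e.left))
    ]
    with open(path, "w") as fh:
        json.dump({"coordinates": "1-based, closed", "events": payload}, fh, indent=1)


def read_variants(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a putative-variant table (clone, chrom, pos, type) from TSV or VCF.

    ``dialect`` is inferred from the extension when None.  In VCF input each
    sample column is a clone; any non-reference, non-missing genotype at a
    record contributes one variant row, typed SNM or indel from the
    REF/ALT lengths.
    """
    path = Path(path)
    if dialect is None:
        dialect = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if dialect == "tsv":
        return pd.read_csv(path, sep="\t", comment="#")
    if dialect != "vcf":
        raise ValueError("dialect must be 'tsv' or 'vcf'")
    clones: list[str] | None = None
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                clones = line.split("\t")[9:]
                continue
            if clones is None:
                raise ValueError(f"{path}: not a VCF (no #CHROM line)")
            parts = line.split("\t")
            chrom, pos, ref = parts[0], int(parts[1]), parts[3]
            alts = parts[4].split(",")
            kind = "SNM" if all(len(a) == len(ref) == 1 for a in alts) else "indel"
            for clone, token in zip(clones, parts[9:]):
                gt = token.split(":")[0]
                if gt not in (".", "./.", "0/0", "0|0"):
                    rows.append({"clone": clone, "chrom": chrom,
                                 "pos": pos, "type": kind})
    return pd.DataFrame(rows, columns=["clone", "chrom", "pos", "type"])


# -- simulator ground truth as JSON -----------------------------------------

def write_truth_json(truth: CohortTruth, path: str | Path) -> None:
    payload = {
        clone: {
            "events": [
                {"chrom": e.chrom, "start": e.start, "end": e.end,
                 "class": e.kind, "homolog": e.homolog,
                 "footprint": e.footprint.tolist()}
                for e in ct.events
            ],
            "mutations": [
                {"chrom": m.chrom, "pos": m.position, "type": m.kind}
                for m in ct.mutations
            ],
        }
        for clone, ct in truth.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_truth_json(path: str | Path) -> CohortTruth:
    with open(path) as fh:
        payload = json.load(fh)
    truth: CohortTruth = {}
    for clone, entry in payload.items():
        events = [
            TrueEvent(ev["chrom"], ev["start"], ev["end"], ev["class"],
                      ev["homolog"], np.asarray(ev["footprint"], dtype=np.int64))
            for ev in entry["events"]
        ]
        mutations = [TrueMutation(m["chrom"], m["pos"], m["type"])
                     for m in entry["mutations"]]
        truth[clone] = CloneTruth(events, mutations)
    return truth
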