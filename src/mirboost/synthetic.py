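"""Synthetic fixtures: PPI edge lists, target tables, gene lists, GMT, ID maps.

Everything the pipeline reads can be generated here with planted structure,
so every stage is testable offline and recovery is measurable against known
ground truth.  The protein network uses preferential attachment by default
(PPI degree distributions are heavy-tailed, and hub analysis needs hubs):
growth starts from a connected seed pair and each arriving node attaches
``m`` edges to distinct existing nodes chosen proportionally to degree, so a
graph with ``n`` nodes has exactly ``1 + m * (n - 2)`` edges.  Edge
confidence scores are uniform integers in 150-999, the familiar
combined-score range, so top-fraction filtering is meaningful.

A "case" bundle plants a connected module whose first half are made both
differentially expressed and miRNA targets (hence seeds); the other half can
only be reached through propagation.  One gene-set term coincides exactly
with the planted module — the discoverable pathway — and the remaining
terms are random draws.  Ground truth (module members, seed members,
planted term IDs) is written alongside.

All generators are bit-reproducible under a fixed ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = ["FixtureSpec", "CaseBundle", "generate_ppi", "generate_target_db", "generate_case"]

SCORE_LOW, SCORE_HIGH = 150, 999  # STRING-like combined-score range


@dataclass
class FixtureSpec:
    """Knobs for fixture generation; defaults are the study conditions."""

    n_genes: int = 500
    n_mirnas: int = 20
    ppi_model: str = "preferential_attachment"  # or "erdos_renyi"
    ppi_params: dict = field(default_factory=lambda: {"m": 3})
    target_density: int = 25  # expected targets per miRNA
    planted_module_size: int = 20
    planted_term_count: int = 1  # module-derived GMT terms; first = the module
    random_term_count: int = 40
    n_ders: int = 5
    deg_extra: int = 40  # differentially expressed genes outside the module
    dialect_noise: bool = True  # emit unsuffixed-miRNA rows to exercise arm expansion
    planted: bool = True  # False: seeds still exist, but no module wiring or aligned term
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_mirnas, self.planted_module_size) < 1:
            raise ValueError("all counts must be positive")
        if self.target_density > self.n_genes:
            raise ValueError("target_density cannot exceed n_genes")
        if self.planted_module_size > self.n_genes:
            raise ValueError("planted module larger than the gene pool")


@dataclass
class CaseBundle:
    """Paths to one generated case plus its ground truth."""

    ppi: Path
    target_db: Path
    deg_list: Path
    der_list: Path
    gmt: Path
    id_map: Path
    known_mirnas: Path
    ground_truth: dict


def _entrez(i: int) -> int:
    return 1001 + i


def _symbol(i: int) -> str:
    return f"GENE{i:04d}"


def _mirna_name(j: int, arm: str) -> str:
    return f"hsa-miR-{100 + j}-{arm}"


def _pa_edges(n: int, m: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Preferential attachment from a seed pair; m edges per arrival."""
    if n < 2:
        raise ValueError("need at least 2 nodes")
    edges = [(0, 1)]
    repeated = [0, 1]  # degree-weighted urn
    for new in range(2, n):
        targets: set[int] = set()
        while len(targets) < min(m, new):
            targets.add(repeated[rng.integers(len(repeated))])
        for t in sorted(targets):
            edges.append((t, new))
            repeated.extend((t, new))
    return edges


def _graph_edges(spec: FixtureSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    if spec.ppi_model == "preferential_attachment":
        return _pa_edges(spec.n_genes, int(spec.ppi_params.get("m", 3)), rng)
    if spec.ppi_model == "erdos_renyi":
        p = float(spec.ppi_params.get("p", 0.02))
        g = nx.gnp_random_graph(
            spec.n_genes, p, seed=int(rng.integers(2**31 - 1))
        )
        return sorted(g.edges())
    raise ValueError(f"unknown ppi_model {spec.ppi_model!r}")


def generate_ppi(
    spec: FixtureSpec,
    out_path: str | Path,
    extra_edges: list[tuple[int, int]] | None = None,
) -> Path:
    """Write a STRING-dialect scored edge list for the fixture network."""
    rng = np.random.default_rng(spec.rng_seed)
    edges = _graph_edges(spec, rng)
    seen = {tuple(sorted(e)) for e in edges}
    for e in extra_edges or []:
        key = tuple(sorted(e))
        if key not in seen and key[0] != key[1]:
            seen.add(key)
            edges.append(e)
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("protein1 protein2 combined_score\n")
        for a, b in edges:
            score = int(rng.integers(SCORE_LOW, SCORE_HIGH + 1))
            fh.write(f"{_symbol(a)} {_symbol(b)} {score}\n")
    return out_path


def generate_target_db(
    spec: FixtureSpec,
    out_path: str | Path,
    forced_targets: dict[int, list[int]] | None = None,
) -> Path:
    """Write a generic-dialect miRNA-target TSV.

    Each miRNA samples ``target_density`` target genes without replacement;
    ``forced_targets`` (miRNA index -> gene indices) injects planted
    interactions on top.  With ``dialect_noise`` on, at least one row uses an
    unsuffixed miRNA name so readers must exercise arm expansion.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    rows: list[tuple[str, str]] = []
    for j in range(spec.n_mirnas):
        arm = "5p" if j % 2 == 0 else "3p"
        name = _mirna_name(j, arm)
        genes = set(rng.choice(spec.n_genes, size=spec.target_density, replace=False))
        genes |= set((forced_targets or {}).get(j, []))
        for g in sorted(genes):
            rows.append((name, _symbol(g)))
    if spec.dialect_noise and rows:
        # duplicate the first row with the arm suffix stripped
        name, gene = rows[0]
        rows.append((name.rsplit("-", 1)[0], gene))
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        fh.write("mirna\ttarget\n")
        for name, gene in rows:
            fh.write(f"{name}\t{gene}\n")
    return out_path


def _write_id_map(spec: FixtureSpec, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("symbol\taliases\tentrez\n")
        for i in range(spec.n_genes):
            alias = f"ALIAS{i:04d}" if i % 7 == 0 else ""
            fh.write(f"{_symbol(i)}\t{alias}\t{_entrez(i)}\n")


def _write_known_mirnas(spec: FixtureSpec, path: Path) -> None:
    with open(path, "w") as fh:
        for j in range(spec.n_mirnas):
            for arm in ("5p", "3p"):
                fh.write(_mirna_name(j, arm) + "\n")


def generate_case(spec: FixtureSpec, out_dir: str | Path) -> CaseBundle:
    """Generate a full input bundle with a planted, discoverable module.

    The module is a connected, densely wired subgraph.  Its first half
    ("seed half") is put on the differentially-expressed-gene list and made
    a target of every differentially expressed miRNA, so the pipeline's
    intersection seeds fall inside the module; the second half is reachable
    only through network propagation.  The first gene-set term equals the
    module exactly.

    With ``planted=False`` the seed overlap is still guaranteed (so the
    pipeline runs), but no module edges are added and every gene-set term is
    a random draw — a structure-free negative control.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed + 2)

    module = sorted(
        int(g)
        for g in rng.choice(spec.n_genes, size=spec.planted_module_size, replace=False)
    )
    n_seed_half = (spec.planted_module_size + 1) // 2
    seed_half = module[:n_seed_half]

    # Wire the module as a dense community (biological modules are dense):
    # a ring guarantees connectivity, then each remaining pair joins with
    # probability 1/2.  Unplanted controls add no edges.
    module_edges: list[tuple[int, int]] = []
    if spec.planted:
        for i in range(len(module)):
            module_edges.append((module[i], module[(i + 1) % len(module)]))
        for i in range(len(module)):
            for j in range(i + 1, len(module)):
                if rng.random() < 0.5:
                    module_edges.append((module[i], module[j]))

    ppi = generate_ppi(spec, out_dir / "ppi_links.txt", extra_edges=module_edges)

    forced = {j: list(seed_half) for j in range(spec.n_ders)}
    target_db = generate_target_db(spec, out_dir / "targets.tsv", forced_targets=forced)

    deg_extra = [
        int(g)
        for g in rng.choice(spec.n_genes, size=spec.deg_extra, replace=False)
        if g not in set(module)
    ]
    degs = sorted(set(seed_half) | set(deg_extra))
    deg_list = out_dir / "degs.txt"
    deg_list.write_text("".join(_symbol(g) + "\n" for g in degs))

    der_list = out_dir / "ders.txt"
    der_names = [
        _mirna_name(j, "5p" if j % 2 == 0 else "3p") for j in range(spec.n_ders)
    ]
    der_list.write_text("".join(name + "\n" for name in der_names))

    # Gene sets: planted term(s) from the module, then random background terms.
    gmt = out_dir / "pathways.gmt"
    planted_term_ids = []
    n_planted_terms = spec.planted_term_count if spec.planted else 0
    with open(gmt, "w") as fh:
        # Term 0 is the whole module; further planted terms are disjoint
        # slices of it, so that no single random gene draw can resemble
        # many of them at once (nested terms would be pathologically
        # correlated under a size-matched null).
        slice_size = (
            max(3, spec.planted_module_size // (n_planted_terms - 1))
            if n_planted_terms > 1
            else 0
        )
        for t in range(n_planted_terms):
            tid = f"PLANTED:{t:04d}"
            planted_term_ids.append(tid)
            if t == 0:
                members = list(module)
            else:
                start = ((t - 1) * slice_size) % spec.planted_module_size
                members = [
                    module[(start + i) % spec.planted_module_size]
                    for i in range(slice_size)
                ]
            fh.write(
                "\t".join([tid, f"planted pathway {t}"] + [_symbol(g) for g in members])
                + "\n"
            )
        for t in range(spec.random_term_count):
            size = int(rng.integers(10, 31))
            members = sorted(rng.choice(spec.n_genes, size=size, replace=False))
            fh.write(
                "\t".join(
                    [f"RAND:{t:04d}", f"background pathway {t}"]
                    + [_symbol(g) for g in members]
                )
                + "\n"
            )

    id_map = out_dir / "id_map.tsv"
    _write_id_map(spec, id_map)
    known = out_dir / "known_mirnas.txt"
    _write_known_mirnas(spec, known)

    ground_truth = {
        "module_entrez": [_entrez(g) for g in module],
        "seed_half_entrez": [_entrez(g) for g in seed_half],
        "planted_terms": planted_term_ids,
        "der_names": der_names,
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))

    return CaseBundle(
        ppi=ppi,
        target_db=target_db,
        deg_list=deg_list,
        der_list=der_list,
        gmt=gmt,
        id_map=id_map,
        known_mirnas=known,
        ground_truth=ground_truth,
    )
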