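"""Deterministic synthetic fixtures: clusters with planted motifs, screening
templates, and noisy peak lists.

Every generator is seeded and byte-reproducible: the same (spec, seed) always
yields the same bundle.  Domain sequences start from the packaged reference
scaffolds, plant the architecture spec's motif residues at the anchor columns,
then apply neutral point substitutions to a fixed fraction of the remaining
positions (never inside an anchor or its 2-residue guard band), so generated
domains are non-identical to the scaffolds while the planted ground truth
stays readable.  The default 10% substitution rate emulates the within-cluster
divergence of paralogous PKS domains while staying far above the annotator's
20% identity floor.

Ground truth (the architecture spec) is emitted separately from the inputs so
annotator tests run blind.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .cluster_model import (
    AA20,
    ArchitectureSpec,
    ClusterModel,
    DomainRecord,
    DomainSpec,
    GeneRecord,
    ModuleRecord,
    ModuleSpec,
    write_cluster_fasta,
)
from .errors import ValidationError
from .ms_adducts import Formula, PACKAGED_ADDUCTS, Peak, PeakList, adduct_mz
from .scaffolds import DEFAULT_SCAFFOLDS, SCAFFOLD_VERSION, ReferenceScaffold, protected_columns

_DATA = Path(__file__).parent / "data"

GENERATOR_VERSION = "1.0"

DEFAULT_MUTATION_RATE = 0.10

#: fraction of the KR NADPH window removed when a deletion is planted
_NADPH_DELETION_SPAN = 12


def mad_architecture() -> ArchitectureSpec:
    """The packaged canonical architecture of the mad cluster (LM + 14 modules)."""
    return ArchitectureSpec.from_json(_DATA / "mad_architecture.json")


def tetromadurin_decomposition() -> dict:
    """The packaged retrobiosynthetic decomposition of the final metabolite."""
    return json.loads((_DATA / "tetromadurin_decomposition.json").read_text())


# ---------------------------------------------------------------------------
# Cluster fixtures
# ---------------------------------------------------------------------------

def _plant(scaffold: ReferenceScaffold, spec: DomainSpec, rng: random.Random) -> str:
    """Plant a domain spec's motif state into a scaffold copy."""
    seq = list(scaffold.sequence)
    kind = spec.kind
    st = spec.state
    if kind == "KS":
        seq[scaffold.anchors["catalytic_cys"][0]] = st["ks_residue"]
    elif kind == "AT":
        for col, res in zip(scaffold.anchors["selectivity_motif"], st["at_motif"]):
            seq[col] = res
    elif kind == "DH":
        seq[scaffold.anchors["ygp_tyr"][0]] = "Y" if st["ygp_tyr"] else "F"
        seq[scaffold.anchors["catalytic_asp"][0]] = "D" if st["catalytic_asp"] else "E"
    elif kind == "KR":
        seq[scaffold.anchors["catalytic_tyr"][0]] = "Y" if st["catalytic_tyr"] else "F"
        ldd_cols = scaffold.anchors["ldd"]
        if st["ldd"]:
            seq[ldd_cols[0]] = rng.choice("LVI")
            seq[ldd_cols[1]] = seq[ldd_cols[2]] = "D"
        else:
            seq[ldd_cols[0]], seq[ldd_cols[1]], seq[ldd_cols[2]] = "A", "G", "E"
        seq[scaffold.anchors["tyr_plus2"][0]] = "P" if st["pro_at_tyr_plus2"] else "A"
    elif kind == "ER":
        seq[scaffold.anchors["key_tyr"][0]] = "Y" if st["key_tyr"] else "F"
    return "".join(seq)


def _mutate(
    seq: str, scaffold: ReferenceScaffold, rate: float, rng: random.Random
) -> str:
    """Neutral substitutions at ``rate`` of the unprotected positions."""
    protected = protected_columns(scaffold)
    eligible = [i for i in range(len(seq)) if i not in protected]
    n = round(rate * len(eligible))
    chars = list(seq)
    for i in sorted(rng.sample(eligible, min(n, len(eligible)))):
        chars[i] = rng.choice([a for a in AA20 if a != chars[i]])
    return "".join(chars)


def _apply_nadph_deletion(seq: str, scaffold: ReferenceScaffold) -> str:
    """Remove most of the KR NADPH window (a 'significant deletion')."""
    cols = sorted(scaffold.anchors["nadph_window"])[:_NADPH_DELETION_SPAN]
    keep = set(range(len(seq))) - set(cols)
    return "".join(ch for i, ch in enumerate(seq) if i in keep)


def make_domain(
    spec: DomainSpec,
    rng: random.Random,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    scaffolds: dict[str, ReferenceScaffold] = DEFAULT_SCAFFOLDS,
) -> str:
    scaffold = scaffolds[spec.kind]
    seq = _plant(scaffold, spec, rng)
    seq = _mutate(seq, scaffold, mutation_rate, rng)
    if spec.kind == "KR" and spec.state["nadph_deletion"]:
        seq = _apply_nadph_deletion(seq, scaffold)
    return seq


@dataclass
class FixtureBundle:
    """A generated cluster fixture: inputs plus separately-held ground truth."""

    cluster: ClusterModel
    module_map: dict
    truth: ArchitectureSpec
    manifest: dict

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write cluster.faa / module_map.json / architecture.json / manifest.json."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": out / "cluster.faa",
            "module_map": out / "module_map.json",
            "truth": out / "architecture.json",
            "manifest": out / "manifest.json",
        }
        write_cluster_fasta(self.cluster, paths["fasta"])
        paths["module_map"].write_text(json.dumps(self.module_map, indent=1, sort_keys=True) + "\n")
        self.truth.to_json(paths["truth"])
        paths["manifest"].write_text(json.dumps(self.manifest, indent=1, sort_keys=True) + "\n")
        return paths

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for g in self.cluster.genes:
            h.update(g.gene_id.encode())
            h.update((g.sequence or "").encode())
        h.update(json.dumps(self.module_map, sort_keys=True).encode())
        return h.hexdigest()


def make_cluster(
    spec: ArchitectureSpec,
    seed: int,
    mutation_rate: float = DEFAULT_MUTATION_RATE,
    scaffolds: dict[str, ReferenceScaffold] = DEFAULT_SCAFFOLDS,
) -> FixtureBundle:
    """Generate a synthetic cluster whose annotation reproduces ``spec``.

    PKS genes carry their modules' domains concatenated in canonical order;
    the module map records each domain's 0-based half-open coordinates.
    Tailoring genes get seeded random sequences of plausible length.
    """
    rng = random.Random(seed)
    gene_parts: dict[str, list[tuple[str, str, str]]] = {}  # gene -> (module, kind, seq)
    for mod in spec.modules:
        for dom in mod.domains:
            seq = make_domain(dom, rng, mutation_rate, scaffolds)
            gene_parts.setdefault(mod.gene_id, []).append((mod.module_index, dom.kind, seq))

    genes: list[GeneRecord] = []
    modules: dict[str, ModuleRecord] = {}
    map_modules: list[dict] = []
    gene_labels: dict[str, str] = {}
    for gene_id, parts in gene_parts.items():
        offset = 0
        full: list[str] = []
        per_module: dict[str, list[dict]] = {}
        for module_index, kind, seq in parts:
            per_module.setdefault(module_index, []).append(
                {"kind": kind, "start": offset, "end": offset + len(seq)}
            )
            modules.setdefault(
                module_index, ModuleRecord(module_index=module_index, gene_id=gene_id)
            ).domains.append(
                DomainRecord(domain_kind=kind, sequence=seq, module_index=module_index)
            )
            full.append(seq)
            offset += len(seq)
        gene_labels[gene_id] = "PKS"
        genes.append(GeneRecord(gene_id=gene_id, product_label="PKS", sequence="".join(full)))
        for module_index, domains in per_module.items():
            map_modules.append(
                {"module_index": module_index, "gene_id": gene_id, "domains": domains}
            )
    for t in spec.tailoring_genes:
        label = t.get("product_label", "other")
        length = rng.randint(150, 500)
        seq = "".join(rng.choice(AA20) for _ in range(length))
        genes.append(GeneRecord(gene_id=t["gene_id"], product_label=label, sequence=seq))
        gene_labels[t["gene_id"]] = label

    from .cluster_model import module_sort_key

    ordered = sorted(modules.values(), key=lambda m: module_sort_key(m.module_index))
    cluster = ClusterModel(cluster_id=spec.cluster_id, genes=genes, pks_modules=ordered)
    module_map = {
        "cluster_id": spec.cluster_id,
        "gene_labels": gene_labels,
        "modules": sorted(map_modules, key=lambda m: module_sort_key(m["module_index"])),
    }
    manifest = {
        "generator_version": GENERATOR_VERSION,
        "scaffold_version": SCAFFOLD_VERSION,
        "seed": seed,
        "mutation_rate": mutation_rate,
        "cluster_id": spec.cluster_id,
        "n_modules": len(spec.modules),
    }
    return FixtureBundle(cluster=cluster, module_map=module_map, truth=spec, manifest=manifest)


# ---------------------------------------------------------------------------
# Random architectures (for blind-recovery property tests)
# ---------------------------------------------------------------------------

_AT_MOTIF_POOL = {
    "acetate": ["HAFH", "TAFH", "VAFH", "YAFH"],
    "propionate": ["YASH", "VASH", "WASH"],
    "relaxed_hybrid": ["HASH"],
}


def random_architecture(
    seed: int, n_extensions: Optional[int] = None, cluster_id: Optional[str] = None
) -> ArchitectureSpec:
    """Draw a random architecture from the supported motif-state vocabulary."""
    rng = random.Random(seed)
    if n_extensions is None:
        n_extensions = rng.randint(3, 8)
    modules: list[ModuleSpec] = []
    # loading module
    modules.append(
        ModuleSpec(
            module_index="LM",
            gene_id="synA1",
            domains=[
                DomainSpec("KS", {"ks_residue": rng.choice(["Q", "Q", "C"])}),
                DomainSpec("AT", {"at_motif": rng.choice(sum(_AT_MOTIF_POOL.values(), []))}),
                DomainSpec("ACP"),
            ],
        )
    )
    gene_n = 1
    for i in range(1, n_extensions + 1):
        if rng.random() < 0.4:
            gene_n += 1
        domains = [
            DomainSpec("KS", {"ks_residue": rng.choice(["C"] * 8 + ["Q", "A"])}),
            DomainSpec(
                "AT",
                {"at_motif": rng.choice(_AT_MOTIF_POOL["acetate"] + _AT_MOTIF_POOL["propionate"])},
            ),
        ]
        if rng.random() < 0.7:
            domains.append(
                DomainSpec(
                    "DH",
                    {"ygp_tyr": rng.random() < 0.8, "catalytic_asp": rng.random() < 0.9},
                )
            )
        if rng.random() < 0.3:
            domains.append(DomainSpec("ER", {"key_tyr": rng.random() < 0.5}))
        if rng.random() < 0.9:
            domains.append(
                DomainSpec(
                    "KR",
                    {
                        "catalytic_tyr": rng.random() < 0.8,
                        "ldd": rng.random() < 0.8,
                        "pro_at_tyr_plus2": rng.random() < 0.2,
                        "nadph_deletion": rng.random() < 0.1,
                    },
                )
            )
        domains.append(DomainSpec("ACP"))
        modules.append(ModuleSpec(module_index=str(i), gene_id=f"synA{gene_n}", domains=domains))
    return ArchitectureSpec(
        cluster_id=cluster_id or f"syn{seed}",
        modules=modules,
        tailoring_genes=[{"gene_id": "synReg", "product_label": "regulator"}],
    )


def expected_calls(spec: ArchitectureSpec) -> dict[tuple[str, str], dict]:
    """Ground-truth (module, kind) -> expected call fields implied by a spec."""
    import re

    truth: dict[tuple[str, str], dict] = {}
    for mod in spec.modules:
        for dom in mod.domains:
            st = dom.state
            key = (mod.module_index, dom.kind)
            if dom.kind == "KS":
                r = st["ks_residue"]
                truth[key] = {
                    "subtype": "KSQ" if r == "Q" else "extension",
                    "active": r in ("C", "Q"),
                }
            elif dom.kind == "AT":
                m = st["at_motif"]
                if m == "HASH":
                    sub = "relaxed_hybrid"
                elif re.match(r"^[HTVY]AFH$", m):
                    sub = "acetate"
                elif re.match(r"^[YVW]ASH$", m):
                    sub = "propionate"
                else:
                    sub = "unknown"
                truth[key] = {"subtype": sub, "active": sub != "unknown"}
            elif dom.kind == "DH":
                active = st["ygp_tyr"] and st["catalytic_asp"]
                truth[key] = {"subtype": "active" if active else "inactive", "active": active}
            elif dom.kind == "KR":
                if not st["catalytic_tyr"] or st["nadph_deletion"]:
                    truth[key] = {"subtype": "inactive", "active": False, "stereo_outcome": "none"}
                elif st["ldd"]:
                    truth[key] = {
                        "subtype": "B2" if st["pro_at_tyr_plus2"] else "B1",
                        "active": True,
                        "stereo_outcome": "D",
                    }
                else:
                    truth[key] = {"subtype": "A", "active": True, "stereo_outcome": "L"}
            elif dom.kind == "ER":
                truth[key] = {
                    "subtype": "L_configuring" if st["key_tyr"] else "D_configuring",
                    "stereo_outcome": "L" if st["key_tyr"] else "D",
                }
    return truth


def random_chain(seed: int, n_extensions: Optional[int] = None):
    """A random but invariant-respecting linear chain (for property tests)."""
    from .chain_assembler import LinearChain, MonomerState
    from .domain_annotator import EXTENDERS

    rng = random.Random(seed)
    if n_extensions is None:
        n_extensions = rng.randint(0, 12)
    starter = MonomerState(
        position="LM", extender=EXTENDERS[rng.choice(["acetate", "propionate"])]
    )
    extensions = []
    for i in range(1, n_extensions + 1):
        ext = EXTENDERS[rng.choice(["acetate", "propionate", "methoxymalonate"])]
        beta = rng.choice(["ketone", "hydroxyl", "enoyl_double_bond", "methylene"])
        alpha = ext.side_group
        extensions.append(
            MonomerState(
                position=str(i),
                extender=ext,
                beta_state=beta,
                beta_stereo=rng.choice("DL") if beta == "hydroxyl" else "none",
                alpha_substituent=alpha,
                alpha_stereo=(
                    rng.choice(["D", "L", "none"])
                    if alpha == "methyl" and beta != "enoyl_double_bond"
                    else "none"
                ),
            )
        )
    return LinearChain(starter=starter, extensions=extensions, provenance="from_target")


# ---------------------------------------------------------------------------
# Nucleotide templates for screening-PCR fixtures
# ---------------------------------------------------------------------------

def _revcomp(seq: str) -> str:
    from Bio.Seq import Seq

    return str(Seq(seq).reverse_complement())


def make_template(
    length: int,
    fwd: str,
    rev: str,
    fwd_start: int,
    rev_end: int,
    deletion: Optional[tuple[int, int]] = None,
    seed: int = 0,
    gc: float = 0.70,
) -> str:
    """A seeded GC-rich template with planted primer sites.

    ``fwd`` is planted at ``fwd_start``; the reverse complement of ``rev``
    ends at ``rev_end`` (so the wild-type amplicon is ``rev_end - fwd_start``
    nt, inclusive of both primer footprints).  An optional ``deletion``
    (start, length) removes template between the primer sites.  The default
    0.70 GC fraction mimics actinomycete genomic DNA.
    """
    fwd, rev = fwd.upper(), rev.upper()
    rev_site = _revcomp(rev)
    rev_start = rev_end - len(rev_site)
    if not (0 <= fwd_start and fwd_start + len(fwd) <= rev_start and rev_end <= length):
        raise ValidationError("primer sites overlap or fall outside the template")
    rng = random.Random(seed)
    bases = []
    for _ in range(length):
        bases.append(rng.choice("GC") if rng.random() < gc else rng.choice("AT"))
    seq = list("".join(bases))
    seq[fwd_start : fwd_start + len(fwd)] = fwd
    seq[rev_start:rev_end] = rev_site
    # avoid accidental extra primer sites elsewhere (exact matching downstream)
    text = "".join(seq)
    for site in (fwd, rev_site):
        idx = text.find(site)
        while idx != -1:
            expected = fwd_start if site == fwd else rev_start
            if idx != expected:
                text = text[:idx] + _scramble(text[idx : idx + len(site)], rng) + text[idx + len(site) :]
                idx = text.find(site)
            else:
                idx = text.find(site, idx + 1)
    seq = list(text)
    if deletion is not None:
        del_start, del_len = deletion
        if del_len <= 0:
            raise ValidationError("deletion length must be positive")
        del_end = del_start + del_len
        if del_start < fwd_start + len(fwd) or del_end > rev_start:
            raise ValidationError("deletion overlaps a primer site or flanks")
        seq = seq[:del_start] + seq[del_end:]
    return "".join(seq)


def _scramble(site: str, rng: random.Random) -> str:
    i = rng.randrange(len(site))
    alphabet = [b for b in "ACGT" if b != site[i]]
    return site[:i] + rng.choice(alphabet) + site[i + 1 :]


def write_template_fasta(template: str, path: str | Path, name: str = "template") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(template), 70):
            fh.write(template[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def make_peaks(
    f: Formula | dict,
    adducts: Sequence = PACKAGED_ADDUCTS,
    mz_noise_sd: float = 0.0,
    seed: int = 0,
    mode: str = "average",
) -> PeakList:
    """One peak per adduct at its computed m/z plus seeded Gaussian noise."""
    if mz_noise_sd < 0:
        raise ValidationError("noise sd must be non-negative")
    rng = random.Random(seed)
    peaks = []
    for a in adducts:
        mz = adduct_mz(f, a, mode)
        if mz_noise_sd:
            mz += rng.gauss(0.0, mz_noise_sd)
        intensity = 10 ** rng.uniform(3, 6)
        peaks.append(Peak(mz=mz, intensity=intensity, label=a.name))
    return PeakList(peaks=peaks, source=f"synthetic seed={seed}")
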