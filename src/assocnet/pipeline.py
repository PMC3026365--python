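"""Staged pipeline orchestration, a persistent job queue, and provenance.

The wizard-equivalent flow is: import a collection, parse its collective
BLASTN results, build the association network, screen, then fan out into
any number of alignment configurations and, per alignment, any number of
tree configurations. Every stage writes its artifact under a workspace
directory and records the complete parameter set it consumed (defaults
included) in a permanent provenance record, so any run can be replayed
and must reproduce its artifacts byte for byte.

The queue is a single transactional JSON state file plus FIFO semantics:
jobs move queued -> running -> done|failed, a failure never touches
other jobs' artifacts, and a process restart loses nothing.
"""

from __future__ import annotations

import datetime
import hashlib
import io
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .blast_io import parse_blast
from .errors import ValidationError
from .network import (
    EdgeGate,
    build_network,
    export_edge_list,
    export_graphml,
    export_report_doc,
)
from .phylo import (
    distance_matrix,
    neighbor_joining,
    newick_string,
    phylip_string,
    render_svg,
    star_align,
)
from .screening import (
    ScreeningCriteria,
    apply_screening,
    load_subject_db,
    select_sequences,
)
from .seqio import fasta_string, read_collection, read_fasta

STAGES = ("import", "blast", "screen", "align", "tree", "full")

SUBDIRS = (
    "collections", "blast", "networks", "reports",
    "alignments", "trees", "provenance", "queue",
)


def _utcnow() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


def sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


class Workspace:
    """On-disk run directory with the documented stage layout."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        for sub in SUBDIRS:
            (self.root / sub).mkdir(parents=True, exist_ok=True)

    def path(self, *parts: str) -> Path:
        return self.root.joinpath(*parts)

    def write_text(self, relpath: str, text: str) -> Path:
        p = self.root / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        p.write_text(text)
        return p


# ---------------------------------------------------------------------------
# Provenance
# ---------------------------------------------------------------------------

@dataclass
class StageRecord:
    stage: str
    params: dict
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    tool: str = f"builtin assocnet/{__version__}"
    started_at: str = ""
    finished_at: str = ""


@dataclass
class ProvenanceRecord:
    run_id: str
    config: dict
    stages: list[StageRecord] = field(default_factory=list)
    package_version: str = __version__
    created_at: str = field(default_factory=_utcnow)

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "package_version": self.package_version,
            "created_at": self.created_at,
            "config": self.config,
            "stages": [vars(s) for s in self.stages],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProvenanceRecord":
        rec = cls(
            run_id=d["run_id"],
            config=d["config"],
            package_version=d.get("package_version", __version__),
            created_at=d.get("created_at", ""),
        )
        rec.stages = [StageRecord(**s) for s in d.get("stages", [])]
        return rec

    def output_checksums(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for s in self.stages:
            out.update(s.outputs)
        return out

    def save(self, workspace: Workspace) -> Path:
        """Write the record; existing records are immutable, so a rerun of
        the same run id gets a numbered sibling file."""
        base = workspace.path("provenance", f"{self.run_id}.json")
        target, k = base, 2
        while target.exists():
            target = workspace.path("provenance", f"{self.run_id}.{k}.json")
            k += 1
        target.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return target


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

_DEFAULT_TREE = {"id": "tree1", "distance_model": "jc69", "clamp_negative": False}
_DEFAULT_ALIGNMENT = {
    "id": "aln1",
    "scores": {"match": 1, "mismatch": -1, "gap": -2},
    "trees": [dict(_DEFAULT_TREE)],
}


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path}: expected a mapping at top level")
    return cfg


def normalize_config(cfg: dict) -> dict:
    """Fill in every defaultable parameter so provenance is complete."""
    out = json.loads(json.dumps(cfg))  # deep copy, JSON-serializable check
    out.setdefault("run_id", "run")
    for section in ("collection", "blast"):
        if section not in out:
            raise ValidationError(f"config lacks required section {section!r}")
    out["collection"].setdefault("format", "fasta")
    out["collection"].setdefault("name", out["run_id"])
    out["blast"].setdefault("format", "tab")
    net = out.setdefault("network", {})
    net.setdefault("gate", EdgeGate().to_dict())
    net["gate"] = EdgeGate.from_dict(net["gate"]).to_dict()
    net.setdefault("count_self_edges", False)
    scr = out.setdefault("screening", {})
    scr.setdefault("min_associations", 2)
    scr.setdefault("include_ids", [])
    scr.setdefault("exclude_ids", [])
    out.setdefault("halt_after_screening", False)
    out.setdefault("subject_db", None)
    alns = out.setdefault("alignments", [json.loads(json.dumps(_DEFAULT_ALIGNMENT))])
    seen_aln: set[str] = set()
    for i, aln in enumerate(alns):
        aln.setdefault("id", f"aln{i + 1}")
        if aln["id"] in seen_aln:
            raise ValidationError(f"duplicate alignment id {aln['id']!r}")
        seen_aln.add(aln["id"])
        scores = aln.setdefault("scores", {})
        for k, v in _DEFAULT_ALIGNMENT["scores"].items():
            scores.setdefault(k, v)
        trees = aln.setdefault("trees", [dict(_DEFAULT_TREE)])
        seen_tree: set[str] = set()
        for j, tr in enumerate(trees):
            tr.setdefault("id", f"tree{j + 1}")
            if tr["id"] in seen_tree:
                raise ValidationError(
                    f"alignment {aln['id']!r}: duplicate tree id {tr['id']!r}"
                )
            seen_tree.add(tr["id"])
            tr.setdefault("distance_model", "jc69")
            tr.setdefault("clamp_negative", False)
    return out


def _read_source(section: dict, what: str) -> str:
    """A config input is either inline text or a file path."""
    if section.get("text") is not None:
        return section["text"]
    if section.get("path"):
        return Path(section["path"]).read_text()
    raise ValidationError(f"config section {what!r} needs 'path' or 'text'")


# ---------------------------------------------------------------------------
# Full pipeline run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: dict, workspace: Workspace) -> ProvenanceRecord:
    """Execute the staged flow and return the saved provenance record."""
    cfg = normalize_config(cfg)
    run_id = cfg["run_id"]
    record = ProvenanceRecord(run_id=run_id, config=cfg)

    def stage(name: str, params: dict) -> StageRecord:
        sr = StageRecord(stage=name, params=params, started_at=_utcnow())
        record.stages.append(sr)
        return sr

    def finish(sr: StageRecord, outputs: list[Path]):
        sr.outputs = {str(p.relative_to(workspace.root)): sha256_file(p) for p in outputs}
        sr.finished_at = _utcnow()

    # -- import ------------------------------------------------------------
    sr = stage("import", dict(cfg["collection"]))
    coll_text = _read_source(cfg["collection"], "collection")
    collection = read_collection(
        cfg["collection"]["name"], coll_text, cfg["collection"]["format"]
    )
    coll_path = workspace.write_text(
        f"collections/{collection.name}.fasta", fasta_string(collection.records)
    )
    finish(sr, [coll_path])

    # -- blast parse ---------------------------------------------------------
    sr = stage("blast", dict(cfg["blast"]))
    blast_text = _read_source(cfg["blast"], "blast")
    results = parse_blast(blast_text, cfg["blast"]["format"])
    fmt = cfg["blast"]["format"]
    blast_path = workspace.write_text(f"blast/{run_id}.blast.{fmt}", blast_text)
    finish(sr, [blast_path])

    # -- network + screening -------------------------------------------------
    gate = EdgeGate.from_dict(cfg["network"]["gate"])
    sr = stage("screen", {**cfg["network"], **cfg["screening"],
                          "halt_after_screening": cfg["halt_after_screening"]})
    net = build_network(results, gate, cfg["network"]["count_self_edges"])
    pregate = (
        net
        if gate == EdgeGate()
        else build_network(results, EdgeGate(), cfg["network"]["count_self_edges"])
    )
    criteria = ScreeningCriteria(
        min_associations=cfg["screening"]["min_associations"],
        gate=gate,
        include_ids=frozenset(cfg["screening"]["include_ids"]),
        exclude_ids=frozenset(cfg["screening"]["exclude_ids"]),
    )
    report = apply_screening(net, criteria, pregate_net=pregate)

    outputs = []
    for suffix, exporter in (
        ("graphml", export_graphml),
        ("edges.tsv", export_edge_list),
        ("network.json", export_report_doc),
    ):
        buf = io.StringIO()
        exporter(net, buf)
        outputs.append(workspace.write_text(f"networks/{run_id}.{suffix}", buf.getvalue()))
    outputs.append(
        workspace.write_text(f"reports/{run_id}.screening.json", report.to_json())
    )
    outputs.append(
        workspace.write_text(f"reports/{run_id}.screening.tsv", report.to_tsv())
    )
    finish(sr, outputs)

    if cfg["halt_after_screening"]:
        record.save(workspace)
        return record

    # -- sequence selection ---------------------------------------------------
    subject_db = None
    if cfg["subject_db"]:
        subject_db = load_subject_db(read_fasta(_read_source(cfg["subject_db"], "subject_db")))
    seqset = select_sequences(report, collection, subject_db=subject_db, net=net)

    # -- alignments and trees (many-to-one fan-out) ----------------------------
    for aln_cfg in cfg["alignments"]:
        sr = stage("align", {"alignment": aln_cfg["id"], **aln_cfg["scores"],
                             "n_sequences": len(seqset.members)})
        aln = star_align(seqset, aln_cfg["scores"])
        aln_path = workspace.write_text(
            f"alignments/{run_id}.{aln_cfg['id']}.phy", phylip_string(aln)
        )
        finish(sr, [aln_path])

        for tree_cfg in aln_cfg["trees"]:
            sr = stage("tree", {"alignment": aln_cfg["id"], **tree_cfg})
            sr.inputs = {
                str(aln_path.relative_to(workspace.root)): sha256_file(aln_path)
            }
            dm = distance_matrix(aln, model=tree_cfg["distance_model"])
            tree = neighbor_joining(dm, clamp_negative=tree_cfg["clamp_negative"])
            base = f"trees/{run_id}.{aln_cfg['id']}.{tree_cfg['id']}"
            t_path = workspace.write_text(base + ".nwk", newick_string(tree))
            s_path = workspace.write_text(base + ".svg", render_svg(tree))
            finish(sr, [t_path, s_path])

    record.save(workspace)
    return record


def replay(record: ProvenanceRecord | str | Path, workspace: Workspace) -> ProvenanceRecord:
    """Re-run a pipeline from its provenance record's stored config."""
    if not isinstance(record, ProvenanceRecord):
        record = ProvenanceRecord.from_dict(json.loads(Path(record).read_text()))
    return run_pipeline(record.config, workspace)


# ---------------------------------------------------------------------------
# Job queue
# ---------------------------------------------------------------------------

@dataclass
class Job:
    id: str
    stage: str
    params: dict
    state: str = "queued"
    submitted_at: str = field(default_factory=_utcnow)
    started_at: str | None = None
    finished_at: str | None = None
    error_message: str | None = None
    artifact_paths: list[str] = field(default_factory=list)


_LEGAL_TRANSITIONS = {
    "queued": {"running"},
    "running": {"done", "failed"},
    "done": set(),
    "failed": set(),
}


class JobQueue:
    """File-backed FIFO queue; the state file is rewritten atomically."""

    def __init__(self, workspace: Workspace):
        self.workspace = workspace
        self.state_path = workspace.path("queue", "state.json")
        if not self.state_path.exists():
            self._write({"next_id": 1, "jobs": []})

    # -- persistence --------------------------------------------------------
    def _read(self) -> dict:
        return json.loads(self.state_path.read_text())

    def _write(self, state: dict) -> None:
        tmp = self.state_path.with_suffix(".json.tmp")
        tmp.write_text(json.dumps(state, indent=2) + "\n")
        os.replace(tmp, self.state_path)

    def _transition(self, job: Job, new_state: str) -> None:
        if new_state not in _LEGAL_TRANSITIONS[job.state]:
            raise ValidationError(
                f"job {job.id}: illegal transition {job.state} -> {new_state}"
            )
        job.state = new_state

    # -- API ----------------------------------------------------------------
    def enqueue(self, stage: str, params: dict) -> Job:
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}")
        json.dumps(params)  # must be serializable
        state = self._read()
        job = Job(id=f"job-{state['next_id']:06d}", stage=stage, params=params)
        state["next_id"] += 1
        state["jobs"].append(vars(job))
        self._write(state)
        return job

    def job_status(self, job_id: str) -> Job:
        for j in self._read()["jobs"]:
            if j["id"] == job_id:
                return Job(**j)
        raise ValidationError(f"unknown job id {job_id!r}")

    def list_jobs(self, state: str | None = None) -> list[Job]:
        jobs = [Job(**j) for j in self._read()["jobs"]]
        if state is not None:
            jobs = [j for j in jobs if j.state == state]
        return jobs

    def run_next(self) -> Job | None:
        """Run the oldest queued job; returns None when the queue is empty.

        A stage failure marks the job failed and leaves the queue and all
        other jobs' artifacts untouched.
        """
        state = self._read()
        entry = next((j for j in state["jobs"] if j["state"] == "queued"), None)
        if entry is None:
            return None
        job = Job(**entry)
        self._transition(job, "running")
        job.started_at = _utcnow()
        entry.update(vars(job))
        self._write(state)

        try:
            artifacts = [str(p) for p in _run_stage(self.workspace, job.stage, job.params)]
            if not artifacts:
                raise ValidationError(f"stage {job.stage!r} produced no artifacts")
            self._transition(job, "done")
            job.artifact_paths = artifacts
        except Exception as exc:  # failure isolation: job fails, queue survives
            job.state = "failed"
            job.error_message = f"{type(exc).__name__}: {exc}"
            job.artifact_paths = []
        job.finished_at = _utcnow()

        state = self._read()
        for j in state["jobs"]:
            if j["id"] == job.id:
                j.update(vars(job))
        self._write(state)
        return self.job_status(job.id)


# ---------------------------------------------------------------------------
# Stage runners for individually queued jobs
# ---------------------------------------------------------------------------

def _run_stage(workspace: Workspace, stage: str, params: dict) -> list[Path]:
    if stage == "full":
        record = run_pipeline(params, workspace)
        return [workspace.path(rel) for rel in record.output_checksums()]
    if stage == "import":
        text = _read_source(params, "import")
        coll = read_collection(
            params.get("name", "collection"), text, params.get("format", "fasta")
        )
        return [
            workspace.write_text(
                f"collections/{coll.name}.fasta", fasta_string(coll.records)
            )
        ]
    if stage == "blast":
        text = _read_source(params, "blast")
        parse_blast(text, params.get("format", "tab"))  # validation
        name = params.get("name", "blast")
        return [
            workspace.write_text(
                f"blast/{name}.blast.{params.get('format', 'tab')}", text
            )
        ]
    if stage in ("screen", "align", "tree"):
        # These run as a halted or full pipeline over the given config.
        cfg = dict(params)
        if stage == "screen":
            cfg["halt_after_screening"] = True
        record = run_pipeline(cfg, workspace)
        return [workspace.path(rel) for rel in record.output_checksums()]
    raise ValidationError(f"unknown stage {stage!r}")


def run_all(queue: JobQueue) -> list[Job]:
    """Drain the queue in FIFO order; returns the finished jobs."""
    finished = []
    while True:
        job = queue.run_next()
        if job is None:
            return finished
        finished.append(job)
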