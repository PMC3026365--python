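"""Adapter contracts for external alignment and tree-inference tools.

The pipeline's own stages are the built-in fallbacks; production runs
plug in ClustalW/MAFFT-class aligners and PHYLIP/PhyML-class tree
programs through these file-exchange contracts:

* an aligner adapter consumes a FASTA file and must return an
  equal-length alignment (FASTA or PHYLIP) readable by this package;
* a tree adapter consumes a sequential PHYLIP alignment and must return
  a Newick tree whose leaf names match the alignment rows;
* a blastn adapter runs a configured blastn command with ``-outfmt 5``
  and stores the raw report verbatim for :mod:`assocnet.blast_io`.

Every adapter invocation records its full command line and parameter map
in the run's provenance. Adapters are never exercised by the test suite.
"""

from __future__ import annotations

import shlex
import subprocess
from dataclasses import dataclass, field

from ..errors import AssocnetError


class AdapterError(AssocnetError):
    pass


@dataclass
class CommandAdapter:
    """Shells out to an external tool via a command template.

    The template is formatted with ``{input}``/``{output}`` plus any
    entries of ``params``; the realized command line is returned so the
    caller can store it in provenance.
    """

    name: str
    command_template: str
    params: dict = field(default_factory=dict)

    def run(self, input_path: str, output_path: str) -> dict:
        cmd = self.command_template.format(
            input=shlex.quote(input_path),
            output=shlex.quote(output_path),
            **self.params,
        )
        proc = subprocess.run(
            cmd, shell=True, capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise AdapterError(
                f"adapter {self.name!r} failed ({proc.returncode}): "
                f"{proc.stderr.strip()[:500]}"
            )
        return {
            "adapter": self.name,
            "command": cmd,
            "params": dict(self.params),
        }


def blastn_adapter(blastn_cmd: str = "blastn", params: dict | None = None) -> CommandAdapter:
    """Adapter contract for a local blastn run producing XML (-outfmt 5)."""
    params = dict(params or {})
    extra = " ".join(f"-{k} {shlex.quote(str(v))}" for k, v in sorted(params.items()))
    template = f"{blastn_cmd} -query {{input}} -outfmt 5 -out {{output}} {extra}".strip()
    return CommandAdapter(name="blastn", command_template=template, params=params)
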