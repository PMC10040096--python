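"""Run configuration: a three-section INI file describing a search.

The configuration names the cloud provider and region, the cluster shape
(maximum node count, instance-type override, preemptible capacity) and
the search itself (program, database, query and result locators, a
pass-through option string).  Every key can also be supplied as a
command-line flag; flags beat file values on conflict.

Sections and keys::

    [cloud-provider]
    cloud = gcp            # or aws
    region = us-east4

    [cluster]
    num-nodes = 4
    use-preemptible = yes          # yes/no/true/false, case-insensitive
    machine-type = e2-highmem-16   # optional override

    [blast]
    program = blastx
    db = refseq_protein
    queries = gs://bucket/queries.fa
    results = gs://bucket/results
    options = -outfmt 7 -evalue 0.01
    batch-len = 5000000            # optional
"""

from __future__ import annotations

import configparser
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator


class Provider(str, Enum):
    aws = "aws"
    gcp = "gcp"


class Program(str, Enum):
    blastn = "blastn"
    megablast = "megablast"
    blastp = "blastp"
    blastx = "blastx"
    tblastn = "tblastn"
    tblastx = "tblastx"

    @property
    def is_nucleotide_query(self) -> bool:
        """True when the query side is untranslated nucleotide."""
        return self in (Program.blastn, Program.megablast)


class ConfigError(ValueError):
    """Malformed or incomplete run configuration."""


SECTION_PROVIDER = "cloud-provider"
SECTION_CLUSTER = "cluster"
SECTION_BLAST = "blast"

_BOOL = {"yes": True, "true": True, "no": False, "false": False}


class RunConfig(BaseModel):
    """Validated run configuration (one search submission)."""

    provider: Provider
    region: str
    num_nodes: int = Field(ge=1, default=1)
    use_preemptible: bool = False
    machine_type: Optional[str] = None
    program: Program
    db: str
    queries: str
    results: str
    options: str = ""
    batch_len: Optional[int] = Field(default=None, ge=1)

    @field_validator("queries", "results", "db")
    @classmethod
    def _non_empty(cls, v: str, info):
        if not v or not v.strip():
            raise ValueError(f"{info.field_name} locator must be non-empty")
        return v

    def render(self) -> str:
        """Serialise back to the INI dialect (inverse of parse_config)."""
        lines = [
            f"[{SECTION_PROVIDER}]",
            f"cloud = {self.provider.value}",
            f"region = {self.region}",
            "",
            f"[{SECTION_CLUSTER}]",
            f"num-nodes = {self.num_nodes}",
            f"use-preemptible = {'yes' if self.use_preemptible else 'no'}",
        ]
        if self.machine_type:
            lines.append(f"machine-type = {self.machine_type}")
        lines += [
            "",
            f"[{SECTION_BLAST}]",
            f"program = {self.program.value}",
            f"db = {self.db}",
            f"queries = {self.queries}",
            f"results = {self.results}",
        ]
        if self.options:
            lines.append(f"options = {self.options}")
        if self.batch_len is not None:
            lines.append(f"batch-len = {self.batch_len}")
        return "\n".join(lines) + "\n"


def _get(cfg: configparser.ConfigParser, section: str, key: str,
         required: bool = True, default: str | None = None) -> str | None:
    if not cfg.has_section(section):
        raise ConfigError(f"missing required section [{section}]")
    if cfg.has_option(section, key):
        return cfg.get(section, key)
    if required:
        raise ConfigError(f"missing required key '{key}' in section [{section}]")
    return default


def _parse_bool(raw: str, key: str) -> bool:
    try:
        return _BOOL[raw.strip().lower()]
    except KeyError:
        raise ConfigError(
            f"key '{key}': expected yes/no/true/false, got {raw!r}") from None


def _parse_int(raw: str, key: str) -> int:
    try:
        value = int(raw)
    except ValueError:
        raise ConfigError(f"key '{key}': expected an integer, got {raw!r}") from None
    if value < 1:
        raise ConfigError(f"key '{key}': must be >= 1, got {value}")
    return value


def parse_config(text: str, overrides: dict[str, str] | None = None) -> RunConfig:
    """Parse configuration file contents into a :class:`RunConfig`.

    ``overrides`` maps key names (e.g. ``"num-nodes"``) to raw string
    values, taking precedence over the file — this is how command-line
    flags are merged in.

    Raises :class:`ConfigError` naming the offending section/key on any
    missing or invalid value.
    """
    cfg = configparser.ConfigParser()
    try:
        cfg.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"malformed configuration: {exc}") from exc

    ov = dict(overrides or {})

    def get(section, key, required=True, default=None):
        if key in ov:
            return ov[key]
        return _get(cfg, section, key, required=required, default=default)

    program_raw = get(SECTION_BLAST, "program")
    try:
        program = Program(program_raw.strip().lower())
    except ValueError:
        supported = ", ".join(p.value for p in Program)
        raise ConfigError(
            f"unknown program {program_raw!r}; supported programs: {supported}"
        ) from None

    provider_raw = get(SECTION_PROVIDER, "cloud")
    try:
        provider = Provider(provider_raw.strip().lower())
    except ValueError:
        raise ConfigError(
            f"unknown cloud provider {provider_raw!r}; supported: aws, gcp"
        ) from None

    num_nodes_raw = get(SECTION_CLUSTER, "num-nodes", required=False, default="1")
    preempt_raw = get(SECTION_CLUSTER, "use-preemptible", required=False, default="no")
    batch_len_raw = get(SECTION_BLAST, "batch-len", required=False)

    return RunConfig(
        provider=provider,
        region=get(SECTION_PROVIDER, "region"),
        num_nodes=_parse_int(num_nodes_raw, "num-nodes"),
        use_preemptible=_parse_bool(preempt_raw, "use-preemptible"),
        machine_type=get(SECTION_CLUSTER, "machine-type", required=False),
        program=program,
        db=get(SECTION_BLAST, "db"),
        queries=get(SECTION_BLAST, "queries"),
        results=get(SECTION_BLAST, "results"),
        options=get(SECTION_BLAST, "options", required=False, default="") or "",
        batch_len=(_parse_int(batch_len_raw, "batch-len")
                   if batch_len_raw is not None else None),
    )
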