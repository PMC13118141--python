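"""Hostname → app → category attribution via unique-domain disambiguation.

App Privacy Report (APR) corpora give a direct app → hostnames mapping.
Raw hostnames mix externally routable domains, local identifiers, and IP
literals; only routable hostnames, reduced to their registered (base)
domain under public-suffix semantics, can be associated with app backends.

Attribution is deliberately conservative: over the union corpus of all APR
sources, only domains contacted by exactly one app are retained (the
"unique-domain map"); domains shared across apps — CDNs, analytics, OS
services — are excluded, so an attributed label can never be wrong by
construction.  The result is a lower bound on app presence and timing, not
an exhaustive accounting of traffic.

Public-suffix rules come from a small bundled snapshot (no network fetch);
pass ``suffix_rules`` explicitly to substitute a fuller rule set.
"""

from __future__ import annotations

import ipaddress
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

REJECT_IP = "non-routable-ip"
REJECT_SINGLE_LABEL = "single-label"
REJECT_SPECIAL_USE = "special-use-suffix"
REJECT_EMPTY = "empty"


@dataclass(frozen=True)
class SuffixRules:
    """Public-suffix rule set: routable suffixes plus rejected special-use ones."""

    public: frozenset[str]
    special_use: frozenset[str]


def load_suffix_rules() -> SuffixRules:
    """Load the bundled public-suffix snapshot."""
    text = resources.files("netrhythm.data").joinpath("public_suffixes.txt").read_text()
    public, special = set(), set()
    for line in text.splitlines():
        line = line.strip().lower()
        if not line or line.startswith("#"):
            continue
        if line.startswith("!"):
            special.add(line[1:])
        else:
            public.add(line)
    return SuffixRules(public=frozenset(public), special_use=frozenset(special))


_DEFAULT_RULES: SuffixRules | None = None


def _rules(suffix_rules: SuffixRules | None) -> SuffixRules:
    global _DEFAULT_RULES
    if suffix_rules is not None:
        return suffix_rules
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = load_suffix_rules()
    return _DEFAULT_RULES


@dataclass(frozen=True)
class Rejection:
    """Rejected hostname with the reason (a return state, not an error)."""

    hostname: str
    reason: str

    def __bool__(self) -> bool:
        return False


def normalize_hostname(
    raw: str, suffix_rules: SuffixRules | None = None
) -> str | Rejection:
    """Reduce a raw hostname to its registered (base) domain, or reject it.

    IP literals, single-label names, and names under special-use suffixes
    (``.local``, ``.test``, ...) are rejected with a reason.  Otherwise the
    hostname is lowercased, a trailing dot is stripped, and it is reduced
    to the registered domain: one label below the longest matching public
    suffix (an unlisted TLD counts as its own public suffix).

    >>> normalize_hostname("video.cdn.youtube.com")
    'youtube.com'
    >>> normalize_hostname("a.b.example.co.uk")
    'example.co.uk'
    """
    rules = _rules(suffix_rules)
    host = (raw or "").strip().lower().rstrip(".")
    if not host:
        return Rejection(raw, REJECT_EMPTY)
    try:
        ipaddress.ip_address(host.strip("[]"))
        return Rejection(raw, REJECT_IP)
    except ValueError:
        pass
    labels = host.split(".")
    if len(labels) < 2 or not all(labels):
        return Rejection(raw, REJECT_SINGLE_LABEL)
    # longest suffix match, checking special-use first at every length
    for i in range(len(labels)):
        cand = ".".join(labels[i:])
        if cand in rules.special_use:
            return Rejection(raw, REJECT_SPECIAL_USE)
    suffix_len = 1  # default rule: unknown TLD is its own public suffix
    for i in range(len(labels) - 1):
        cand = ".".join(labels[i:])
        if cand in rules.public:
            suffix_len = len(labels) - i
            break
    if suffix_len >= len(labels):
        # the whole name is a public suffix (e.g. "co.uk") — nothing registered
        return Rejection(raw, REJECT_SINGLE_LABEL)
    return ".".join(labels[-(suffix_len + 1) :])


@dataclass
class AprReport:
    """One APR corpus: app (bundle_id, name) → raw hostnames contacted."""

    source: str  # 'participant' or 'scripted'
    entries: dict[str, set[str]]  # bundle_id -> raw hostnames
    app_names: dict[str, str] = field(default_factory=dict)


@dataclass
class DomainCorpus:
    """Union corpus: registered domain → set of apps observed contacting it."""

    domain_apps: dict[str, set[str]]
    app_names: dict[str, str]
    rejected: list[Rejection]
    sources: list[str]

    @property
    def n_apps(self) -> int:
        apps: set[str] = set()
        for s in self.domain_apps.values():
            apps |= s
        return len(apps)

    @property
    def n_domains(self) -> int:
        return len(self.domain_apps)


@dataclass
class UniqueDomainMap:
    """Registered domain → exactly one app, plus exclusions with reasons."""

    mapping: dict[str, str]  # domain -> bundle_id
    excluded: dict[str, str]  # domain -> reason ('shared')
    unique_fraction: float
    app_names: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.mapping.items()), columns=["domain", "bundle_id"]
        )


def read_apr_json(payload: list[dict] | dict, source: str) -> AprReport:
    """Build an AprReport from APR-style JSON: [{bundle_id, name, domains}]."""
    if isinstance(payload, dict):
        payload = payload.get("apps", [])
    entries: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    for item in payload:
        bid = item["bundle_id"]
        entries.setdefault(bid, set()).update(item.get("domains", []))
        if item.get("name"):
            names[bid] = item["name"]
    return AprReport(source=source, entries=entries, app_names=names)


def build_corpus(
    reports: Iterable[AprReport], suffix_rules: SuffixRules | None = None
) -> DomainCorpus:
    """Union APR reports into a normalized domain → apps corpus.

    Hostnames are normalized to registered domains; rejected hostnames are
    retained with their reasons.  App sets are merged per domain across all
    sources, so adding a report can only grow a domain's app set.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("build_corpus requires at least one report")
    rules = _rules(suffix_rules)
    domain_apps: dict[str, set[str]] = {}
    app_names: dict[str, str] = {}
    rejected: list[Rejection] = []
    sources: list[str] = []
    for rep in reports:
        sources.append(rep.source)
        app_names.update(rep.app_names)
        for bid, hosts in rep.entries.items():
            for host in hosts:
                dom = normalize_hostname(host, rules)
                if isinstance(dom, Rejection):
                    rejected.append(dom)
                else:
                    domain_apps.setdefault(dom, set()).add(bid)
    return DomainCorpus(
        domain_apps=domain_apps, app_names=app_names, rejected=rejected, sources=sources
    )


def unique_app_domains(corpus: DomainCorpus) -> UniqueDomainMap:
    """Retain domains mapped to exactly one app across the whole corpus.

    Domains contacted by more than one app are excluded as shared
    infrastructure.  The unique fraction (retained / total registered
    domains) is reported alongside the map.
    """
    mapping: dict[str, str] = {}
    excluded: dict[str, str] = {}
    for dom, apps in corpus.domain_apps.items():
        if len(apps) == 1:
            mapping[dom] = next(iter(apps))
        else:
            excluded[dom] = "shared"
    total = len(corpus.domain_apps)
    frac = len(mapping) / total if total else 0.0
    return UniqueDomainMap(
        mapping=mapping, excluded=excluded, unique_fraction=frac, app_names=corpus.app_names
    )


def read_category_map(path) -> dict[str, str]:
    """Read a bundle_id → primary genre CSV (columns bundle_id, name, genre)."""
    frame = pd.read_csv(path)
    if frame["bundle_id"].duplicated().any():
        dupes = frame.loc[frame["bundle_id"].duplicated(), "bundle_id"].tolist()
        raise ValueError(f"duplicate bundle_id in category map: {dupes}")
    return dict(zip(frame["bundle_id"], frame["genre"]))


def attribute(
    flows: pd.DataFrame,
    unique_map: UniqueDomainMap,
    categories: Mapping[str, str] | None = None,
    suffix_rules: SuffixRules | None = None,
) -> pd.DataFrame:
    """Label flows with at most one app (and genre) via the unique-domain map.

    Returns the input frame with added columns ``domain`` (registered domain
    or NA), ``app`` (bundle_id or NA) and ``genre``.  Flows whose hostname
    is rejected, unknown, or maps to a shared-excluded domain stay
    unattributed — the map cannot mislabel by construction.  An attributed
    app missing from the category map gets genre ``"unknown"`` with a
    warning.
    """
    rules = _rules(suffix_rules)
    categories = dict(categories or {})
    hostnames = flows["hostname"].astype(str)
    norm_cache: dict[str, str | None] = {}
    domains: list[str | None] = []
    for h in hostnames:
        if h not in norm_cache:
            d = normalize_hostname(h, rules)
            norm_cache[h] = None if isinstance(d, Rejection) else d
        domains.append(norm_cache[h])
    out = flows.copy()
    out["domain"] = domains
    out["app"] = [unique_map.mapping.get(d) if d else None for d in domains]
    missing_cat: set[str] = set()

    def genre_of(app: str | None) -> str | None:
        if app is None:
            return None
        if app in categories:
            return categories[app]
        missing_cat.add(app)
        return "unknown"

    out["genre"] = [genre_of(a) for a in out["app"]]
    if missing_cat:
        warnings.warn(
            f"apps missing from category map, genre set to 'unknown': {sorted(missing_cat)}",
            stacklevel=2,
        )
    return out


@dataclass
class AttributionCoverage:
    """How much of the traffic the conservative unique-domain map reaches."""

    byte_fraction_up: float  # attributable upload bytes / total upload bytes
    bin_fraction: float  # bins with >=1 attributable flow / bins with >=1 flow
    unique_domain_fraction: float

    def __post_init__(self) -> None:
        for v in (self.byte_fraction_up, self.bin_fraction, self.unique_domain_fraction):
            if not (0.0 <= v <= 1.0 or np.isnan(v)):
                raise ValueError(f"fraction {v} outside [0, 1]")


def attribution_coverage(
    attributed: pd.DataFrame,
    unique_map: UniqueDomainMap | None = None,
    bin_width: int = 10,
) -> AttributionCoverage:
    """Byte- and bin-level attribution coverage.

    ``attributed`` is the output of :func:`attribute` (must span the same
    flow universe as the raw log).  Byte fraction is attributable upload
    bytes over total upload bytes; bin fraction is the share of
    ``bin_width``-minute bins containing at least one flow that also
    contain at least one attributable flow.
    """
    total_up = float(attributed["bytes_up"].sum())
    if total_up <= 0:
        raise ValueError("zero total upload bytes: byte fraction undefined")
    has_app = attributed["app"].notna()
    byte_frac = float(attributed.loc[has_app, "bytes_up"].sum()) / total_up

    ts = pd.DatetimeIndex(attributed["window_start"])
    bin_key = ts.floor(f"{bin_width}min")
    keys = pd.MultiIndex.from_arrays([attributed["participant_id"], bin_key])
    occupied = pd.Series(True, index=keys)
    n_bins = occupied.index.drop_duplicates().size
    attributable_bins = occupied.index[has_app.to_numpy()].drop_duplicates().size
    bin_frac = attributable_bins / n_bins if n_bins else float("nan")

    uniq_frac = unique_map.unique_fraction if unique_map is not None else float("nan")
    return AttributionCoverage(
        byte_fraction_up=byte_frac, bin_fraction=bin_frac, unique_domain_fraction=uniq_frac
    )


_TOKEN_RE = re.compile(r"[a-z0-9]+")


def name_token_identifiable(app_name: str, domain: str) -> bool:
    """Default identifiability predicate: the registered domain's registrable
    label shares an alphanumeric token (length >= 4) with the app name."""
    label = domain.split(".")[0]
    name_tokens = {t for t in _TOKEN_RE.findall(app_name.lower()) if len(t) >= 4}
    dom_tokens = {t for t in _TOKEN_RE.findall(label.lower()) if len(t) >= 4}
    if name_tokens & dom_tokens:
        return True
    squashed = "".join(_TOKEN_RE.findall(app_name.lower()))
    return len(squashed) >= 4 and squashed in label.lower().replace("-", "")


def scripted_vs_deep_overlap(
    scripted: Sequence[AprReport],
    participant: Sequence[AprReport],
    suffix_rules: SuffixRules | None = None,
    identifiable: Callable[[str, str], bool] = name_token_identifiable,
) -> pd.DataFrame:
    """Compare app identifiability from scripted vs naturalistic APRs.

    Restricted to the shared app cohort (apps in both sources), builds a
    per-source corpus and unique-domain map, then flags each app as
    identifiable in a source if that source yields at least one unique
    domain passing the ``identifiable`` predicate against the app name.
    Returns one row per shared app with boolean columns
    ``scripted_identifiable`` and ``participant_identifiable``.
    """
    rules = _rules(suffix_rules)
    s_apps = set().union(*(r.entries.keys() for r in scripted)) if scripted else set()
    p_apps = set().union(*(r.entries.keys() for r in participant)) if participant else set()
    shared = sorted(s_apps & p_apps)
    if not shared:
        raise ValueError("scripted and participant sources share no apps")

    def per_source(reports: Sequence[AprReport]) -> dict[str, set[str]]:
        restricted = [
            AprReport(
                source=r.source,
                entries={b: h for b, h in r.entries.items() if b in shared},
                app_names=r.app_names,
            )
            for r in reports
        ]
        umap = unique_app_domains(build_corpus(restricted, rules))
        by_app: dict[str, set[str]] = {}
        for dom, bid in umap.mapping.items():
            by_app.setdefault(bid, set()).add(dom)
        return by_app

    names: dict[str, str] = {}
    for r in list(scripted) + list(participant):
        names.update(r.app_names)
    s_unique = per_source(scripted)
    p_unique = per_source(participant)

    rows = []
    for bid in shared:
        name = names.get(bid, bid)
        s_ok = any(identifiable(name, d) for d in s_unique.get(bid, ()))
        p_ok = any(identifiable(name, d) for d in p_unique.get(bid, ()))
        rows.append((bid, name, s_ok, p_ok))
    frame = pd.DataFrame(
        rows, columns=["bundle_id", "name", "scripted_identifiable", "participant_identifiable"]
    )
    frame.attrs["n_shared"] = len(shared)
    frame.attrs["n_scripted_identifiable"] = int(frame["scripted_identifiable"].sum())
    frame.attrs["n_participant_identifiable"] = int(frame["participant_identifiable"].sum())
    return frame
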