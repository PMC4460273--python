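"""Bundled study records for the CST3 rs1064039 AMD/AD analyses.

Three small fixtures transcribed from published reports ship with the
package so the whole reproduction pipeline is self-contained:

* the exudative-AMD case-control genotype counts (350 cases genotyped in
  England against 3781 Exome Sequencing Project controls);
* the earlier AMD association study's printed per-genotype summary ORs and
  p-values (167 cases / 517 controls; raw counts never published);
* the AD meta-analysis per-genotype summary ORs and p-values.
"""

from __future__ import annotations

from importlib import resources

from .association import EffectEstimate, read_summary_studies
from .counts import GenotypeCountTable, read_count_tables

# sample sizes of the summary-only AMD study
ZURDEL_N_CASES = 167
ZURDEL_N_CONTROLS = 517


def _data_path(name: str):
    return resources.files("genassoc.data") / name


def leeds_amd_counts() -> GenotypeCountTable:
    """Genotype counts of the 350-case / 3781-control exudative-AMD study."""
    with resources.as_file(_data_path("amd_leeds_counts.tsv")) as path:
        (table,) = read_count_tables(path)
    return table


def zurdel_amd_summary() -> dict[str, EffectEstimate]:
    """Per-genotype summary estimates of the 167/517 AMD study (SEs from p-values)."""
    with resources.as_file(_data_path("amd_zurdel_summary.tsv")) as path:
        return read_summary_studies(path)["zurdel_amd"]


def ad_meta_summary() -> dict[str, EffectEstimate]:
    """Per-genotype summary estimates of the AD meta-analysis (SEs from p-values)."""
    with resources.as_file(_data_path("ad_meta_summary.tsv")) as path:
        return read_summary_studies(path)["ad_meta"]
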