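"""Machine-readable column schemas for every table the pipeline writes."""

from __future__ import annotations

import json
from pathlib import Path

OUTPUT_SCHEMAS: dict[str, list[str]] = {
    "cohort.tsv": [
        "pair_id", "is_case", "age", "fasting_hours", "height_cm",
        "weight_kg", "weight_at_20_kg", "wc_cm", "hc_cm", "education",
        "income", "smoking", "drinking", "physical_activity", "diet_score",
        "t2dm", "cholelithiasis", "hbsag", "chronic_hepatitis", "cirrhosis",
        "met_*",
    ],
    "metabolite_annotations.tsv": ["name", "class", "block"],
    "sumstats.tsv": [
        "snp", "chr", "pos", "effect_allele", "other_allele", "eaf", "beta",
        "se", "pval", "n",
    ],
    "screen_step1.tsv": [
        "metabolite", "exposure", "effect", "ci_low", "ci_high", "se",
        "p_raw", "n_used", "p_nonlinear", "q_fdr", "category", "retained",
    ],
    "screen_step2.tsv": [
        "metabolite", "outcome", "effect", "ci_low", "ci_high", "se",
        "p_raw", "p_nonlinear", "n_used", "n_pairs_dropped", "flag",
        "q_fdr", "category", "retained",
    ],
    "intermediates.tsv": ["metabolite", "n_exposures"],
    "network_edges.tsv": ["node_a", "node_b", "weight"],
    "network_modules.tsv": ["metabolite", "module", "degree"],
    "pathway_results.tsv": [
        "pathway", "size", "overlap", "p_enrich", "impact", "q_fdr",
    ],
    "mediation.tsv": [
        "exposure", "term", "members", "a", "b", "estimate", "ci_low",
        "ci_high",
    ],
    "mr_estimates.tsv": [
        "method", "beta", "se", "ci_low", "ci_high", "pval", "n_snps",
        "intercept", "intercept_p", "q_stat", "q_p", "exposure", "outcome",
    ],
}


def write_schemas(outdir: str | Path) -> Path:
    path = Path(outdir) / "schemas.json"
    path.write_text(json.dumps(OUTPUT_SCHEMAS, indent=2))
    return path
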