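#!/usr/bin/env python
"""Validate the linked genes against the (simulated) eQTL gene sets and
against the generator's ground truth, and compare the observed recall and
precision with the closed-form values implied by the eQTL noise parameters.
Writes results/validation.json.
"""

import json
from pathlib import Path

from loopgene.linker import LinkTable
from loopgene.metrics import eqtl_validation, read_eqtl_sets
from loopgene.synthetic_data import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
SIM = ROOT / "results" / "sim"
LINK = ROOT / "results" / "link"


def main() -> None:
    table = LinkTable.from_tsv(LINK / "link_table.tsv")
    linked = table.gene_sets_by_locus()
    eqtl = read_eqtl_sets(SIM / "eqtl.tsv")
    vr = eqtl_validation(linked, eqtl)
    cfg = SimulationConfig()  # generator defaults = study conditions
    d, s = cfg.eqtl_dropout, cfg.eqtl_spurious_rate
    expected = {"recall": (1 - d) / (1 - d + s), "precision": 1 - d}

    truth = {}
    for line in (SIM / "truth_genes.tsv").read_text().splitlines()[1:]:
        locus, gene = line.split("\t")
        truth.setdefault(locus, set()).add(gene)
    vs_truth = eqtl_validation(linked, truth)

    payload = {
        "vs_eqtl": {"recall": vr.recall, "precision": vr.precision,
                    "n_eqtl_genes": vr.n_eqtl_genes,
                    "n_linked_genes": vr.n_linked_genes},
        "expected_from_noise_rates": expected,
        "vs_truth": {"recall": vs_truth.recall, "precision": vs_truth.precision},
    }
    out = ROOT / "results" / "validation.json"
    out.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {out}")
    print(f"  vs eQTL sets: recall {vr.recall:.1%}, precision (aka specificity) "
          f"{vr.precision:.1%}")
    print(f"  closed-form expectation at dropout {d}, spurious {s}: "
          f"recall {expected['recall']:.1%}, precision {expected['precision']:.1%}")
    print(f"  vs generator truth: recall {vs_truth.recall:.1%}, "
          f"precision {vs_truth.precision:.1%}")


if __name__ == "__main__":
    main()
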