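"""End-to-end orchestration: search -> budget selection -> slice -> retrain -> eval.

The three-step workflow: (1) weights and sparsity masks co-trained by AdamW
under the CE + L1 objective; (2) sites ranked by mask magnitude and the
low-ranked ones removed down to the budget, with patch monotonicity
enforced; (3) the sliced model retrained with the same optimiser settings
and no sparsity penalty.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig
from .io import samples_to_arrays, save_checkpoint
from .model import assemble_model, evaluate, extract_compact, retrain
from .sparsity_search import rank_dimensions, run_search
from .subnet import count_params, enforce_patch_monotonicity, select_budget, SubnetSpec

log = logging.getLogger("dfslim")


def prepare_data(cfg: RunConfig):
    from .synthetic import generate_dataset
    splits, _ = generate_dataset(cfg.seed, cfg.n_phantoms, size=cfg.phantom_size,
                                 noise_sigma=cfg.noise_sigma,
                                 blur_sigma=cfg.blur_sigma)
    return {k: samples_to_arrays(v) for k, v in splits.items()}


def pipeline_run(cfg: RunConfig, out_dir) -> dict:
    """Run the full pipeline, writing all artifacts under ``out_dir``.

    Returns a summary dict with the searched masks, spec and eval report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "data"
    try:
        data = prepare_data(cfg)
        stage = "search"
        model = assemble_model(cfg.model, seed=cfg.seed, search_mode=True)
        result = run_search(model, data["train"], epochs=cfg.search_epochs,
                            seed=cfg.seed, optimizer=cfg.optimizer)
        for e, (ce, l1) in enumerate(zip(result.ce_trace, result.l1_trace), 1):
            log.info("search epoch %d: CE=%.6f L1=%.6f", e, ce, l1)
        save_checkpoint(out / "search_result.npz", model.params,
                        meta={"epochs": result.epochs, "seed": result.seed,
                              "optimizer": vars(result.optimizer)})
        ranking = rank_dimensions(result.masks)
        (out / "mask_scores.json").write_text(json.dumps(
            [{"kind": r.kind, "layer": r.layer, "head": r.head,
              "index": r.index, "score": r.score} for r in ranking], indent=1))

        stage = "extract"
        spec = enforce_patch_monotonicity(select_budget(ranking, cfg.budget))
        spec.to_json(out / "subnet_spec.json")
        full = SubnetSpec.full(cfg.model.search)
        report_params = {
            "searchable_params_before": count_params(full, cfg.model.search),
            "searchable_params_after": count_params(spec, cfg.model.search),
        }

        stage = "retrain"
        compact = extract_compact(model, spec)
        compact = retrain(compact, data["train"], epochs=cfg.retrain_epochs,
                          seed=cfg.seed, optimizer=cfg.optimizer)
        save_checkpoint(out / "compact_model.npz", compact.params,
                        meta={"budget": vars(cfg.budget)})

        stage = "eval"
        report = evaluate(compact, data["test"])
        doc = {**report.as_dict(), **report_params}
        (out / "eval_report.json").write_text(json.dumps(doc, indent=1))
        (out / "run_log.txt").write_text(
            "\n".join(f"search epoch {e}: CE={ce:.6f} L1={l1:.6f}"
                      for e, (ce, l1) in
                      enumerate(zip(result.ce_trace, result.l1_trace), 1)) + "\n")
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err
    return {"search": result, "spec": spec, "report": report,
            "model": compact, "params": report_params}
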