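"""Train on synthetic barrels, then predict strands for held-out proteins.

Prints each predicted transmembrane region next to the planted truth, and
region-level sensitivity/precision over the held-out set.  A true positive
is a prediction overlapping exactly one annotated strand.
"""

from barreltm import BarrelSpec, generate_corpus, predict_protein, train_pipeline
from barreltm.evaluation import format_percent
from barreltm.pipeline import evaluate_predictions, predict_corpus

corpus = generate_corpus(BarrelSpec(), n_proteins=36, seed=11)
train, held = corpus[:30], corpus[30:]
result = train_pipeline(train, seed=11)

demo = held[0]
preds = predict_protein(demo.sequence, result.model, result.table)
print(f"{demo.id}: {demo.sequence.n} residues")
print(f"  planted strands:   {list(demo.tm_regions)}")
print(f"  predicted regions: {[(p.start, p.end) for p in preds]}")

predictions = predict_corpus([p.sequence for p in held], result.model, result.table)
ev = evaluate_predictions(predictions, held)
print(f"\nheld-out proteins: {len(held)}  known strands: {ev.known_regions}")
print(
    f"TP {ev.tp}  FP {ev.fp}  FN {ev.fn}  ->  "
    f"sensitivity {format_percent(ev.sensitivity)}%  "
    f"precision {format_percent(ev.precision)}%  "
    f"segment overlap {format_percent(ev.segment_overlap)}%"
)
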