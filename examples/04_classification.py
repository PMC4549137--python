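"""Cross-validated patient/control classification with the SMO linear SVM.

Selected edges feed a linear soft-margin SVM evaluated by stratified
10-fold cross-validation; sensitivity is the fraction of patients and
specificity the fraction of controls correctly classified.
"""
from scaconn import cross_validate, default_study_spec, generate_cohort
from scaconn.experiments import cohort_edges

spec, _ = default_study_spec()
cohort = generate_cohort(spec, master_seed=1)
edges, labels = cohort_edges(cohort)

for mode in ("nested", "pooled"):
    report = cross_validate(edges, labels, k=10, selection_mode=mode,
                            threshold=0.001, seed=1)
    print(f"{mode:>6}: accuracy {100*report.accuracy:5.1f}%  "
          f"sensitivity {100*report.sensitivity:5.1f}%  "
          f"specificity {100*report.specificity:5.1f}%  "
          f"({report.tp}+{report.tn} of {report.n_tested} correct)")
# "nested" reselects edges inside each training fold (honest); "pooled"
# selects once on all subjects before CV, the protocol many connectivity
# classification studies describe, which is optimistic on null data.
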