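# Depression treatment decision tree: three options (1 = no treatment,
# 2 = cognitive behavioural therapy, 3 = antidepressants).  Probabilities of
# recovery/relapse on option 1 are Beta; log odds ratios shifting them onto
# options 2 and 3 follow two bivariate-Normal posterior approximations from a
# network meta-analysis; 30-year costs (GBP) and QALYs in the terminal states
# are Normal.  Net benefit: wtp * QALYs - costs - c_treat[d].
name: depression
kind: depression_tree
wtp: 20000.0
c_treat: [0.0, 300.0, 30.0]
blocks:
  - {name: p_rec_1, kind: beta, alpha: 6.0, beta: 200.0}
  - {name: p_rel_1, kind: beta, alpha: 2.0, beta: 100.0}
  - kind: mvn
    names: [lorrec_2, lorrec_3]
    mean: [0.99, 1.33]
    cov: [[0.22, 0.15], [0.15, 0.20]]
  - kind: mvn
    names: [lorrel_2, lorrel_3]
    mean: [-1.48, -0.40]
    cov: [[0.14, 0.05], [0.05, 0.11]]
  - {name: c_rec, kind: normal, mean: 1000.0, sd: 50.0}
  - {name: c_rel, kind: normal, mean: 2000.0, sd: 100.0}
  - {name: c_nrec, kind: normal, mean: 2500.0, sd: 125.0}
  - {name: q_rec, kind: normal, mean: 26.0, sd: 2.0}
  - {name: q_rel, kind: normal, mean: 23.0, sd: 3.0}
  - {name: q_nrec, kind: normal, mean: 20.0, sd: 4.0}
subsets:
  probabilities: [p_rec_1, p_rel_1, lorrec_2, lorrec_3, lorrel_2, lorrel_3]
  costs_qalys: [c_rec, c_rel, c_nrec, q_rec, q_rel, q_nrec]
  cbt: [lorrec_2, lorrel_2]
  antidepressant: [lorrec_3, lorrel_3]
  all: [p_rec_1, p_rel_1, lorrec_2, lorrec_3, lorrel_2, lorrel_3,
        c_rec, c_rel, c_nrec, q_rec, q_rel, q_nrec]
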