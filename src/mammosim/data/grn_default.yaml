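genes:
- TP53
- ATM
- HER2
- BRCA1
- AKT1
- ATR
- CHEK1
- MDM2
- CDK2
- P21
k: 0.5
drive_cap: 1000.0
per_gene:
  TP53:
    alpha_g: -1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 1.0
    feedback: negative
    fb_beta: 0.2
    fb_nu: 1.0
    fb_gamma: 1.0
    hill_beta: 0.2
    hill_nu: 1.5
    hill_gamma: 4.0
    bool_threshold: 0.5
    input: oxygen
  ATM:
    alpha_g: -1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 1.0
    feedback: negative
    fb_beta: 0.2
    fb_nu: 1.0
    fb_gamma: 1.0
    hill_beta: 0.2
    hill_nu: 1.5
    hill_gamma: 1.0
    bool_threshold: 0.5
    input: estrogen
  HER2:
    alpha_g: 1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 0.1
    feedback: positive
    fb_beta: 20.0
    fb_nu: 0.5
    fb_gamma: 6.0
    hill_beta: 0.2
    hill_nu: 0.5
    hill_gamma: 3.0
    bool_threshold: 0.5
    input: estrogen
  BRCA1:
    alpha_g: -1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 1.0
    feedback: negative
    fb_beta: 0.2
    fb_nu: 1.0
    fb_gamma: 1.0
    hill_beta: 0.2
    hill_nu: 1.5
    hill_gamma: 1.0
    bool_threshold: 0.5
    input: estrogen
  AKT1:
    alpha_g: 1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 0.1
    feedback: positive
    fb_beta: 20.0
    fb_nu: 0.5
    fb_gamma: 6.0
    hill_beta: 0.2
    hill_nu: 0.5
    hill_gamma: 2.0
    bool_threshold: 0.5
    input: estrogen
  ATR:
    alpha_g: -1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 1.0
    feedback: negative
    fb_beta: 0.2
    fb_nu: 1.0
    fb_gamma: 1.0
    hill_beta: 0.2
    hill_nu: 1.5
    hill_gamma: 1.0
    bool_threshold: 0.5
    input: oxygen
  CHEK1:
    alpha_g: -1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 1.0
    feedback: negative
    fb_beta: 0.2
    fb_nu: 1.0
    fb_gamma: 1.0
    hill_beta: 0.2
    hill_nu: 1.5
    hill_gamma: 1.0
    bool_threshold: 0.5
    input: estrogen
  MDM2:
    alpha_g: 1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 0.1
    feedback: positive
    fb_beta: 20.0
    fb_nu: 0.5
    fb_gamma: 6.0
    hill_beta: 0.2
    hill_nu: 0.5
    hill_gamma: 2.0
    bool_threshold: 0.5
    input: oxygen
  CDK2:
    alpha_g: 1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 0.1
    feedback: positive
    fb_beta: 20.0
    fb_nu: 0.5
    fb_gamma: 6.0
    hill_beta: 0.2
    hill_nu: 0.5
    hill_gamma: 4.0
    bool_threshold: 0.5
    input: oxygen
  P21:
    alpha_g: 1.0
    mu: 0.2
    lambda_g: 0.4
    delta: 0.1
    feedback: positive
    fb_beta: 20.0
    fb_nu: 0.5
    fb_gamma: 6.0
    hill_beta: 0.2
    hill_nu: 0.5
    hill_gamma: 4.0
    bool_threshold: 1.5
    input: estrogen
edges:
- source: CHEK1
  target: TP53
  sign: 1
- source: ATR
  target: TP53
  sign: 1
- source: HER2
  target: TP53
  sign: 1
- source: MDM2
  target: TP53
  sign: -1
- source: TP53
  target: ATM
  sign: 1
- source: ATM
  target: CHEK1
  sign: 1
- source: BRCA1
  target: ATR
  sign: 1
- source: ATR
  target: BRCA1
  sign: 1
- source: CDK2
  target: HER2
  sign: 1
- source: HER2
  target: AKT1
  sign: 1
- source: AKT1
  target: MDM2
  sign: 1
- source: TP53
  target: P21
  sign: 1
- source: AKT1
  target: P21
  sign: 1
- source: CDK2
  target: P21
  sign: 1
- source: AKT1
  target: CDK2
  sign: 1
- source: HER2
  target: CDK2
  sign: 1
- source: P21
  target: CDK2
  sign: -1
- source: TP53
  target: HER2
  sign: -1
- source: BRCA1
  target: HER2
  sign: -1
- source: TP53
  target: CDK2
  sign: -1
- source: CHEK1
  target: CDK2
  sign: -1
- source: ATM
  target: MDM2
  sign: -1
- source: CHEK1
  target: P21
  sign: -1
- source: BRCA1
  target: AKT1
  sign: -1
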