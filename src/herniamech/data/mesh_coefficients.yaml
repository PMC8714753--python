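# Dynamic-stiction coefficients of hernia meshes from dynamic intermittent
# strain (DIS) bench classification.  Class A: high dynamic stiction,
# B: intermediate, C: low.  Coefficients are dimensionless multipliers on
# the repair score.
schema: herniamech-mesh-table/1
meshes:
  - name: Progrip
    dis_class: A
    coefficient: 1.44
    notes: "self-gripping; wet/dry and lubricant conditions can shift coefficients by up to 75%"
  - name: Dynamesh Cicat
    dis_class: A
    coefficient: 1.0
    notes: "anisotropic warp-knit; orientation along the most elastic axis can alter retention force by 50%"
  - name: Ultrapro
    dis_class: B
    coefficient: 0.25
    notes: ""
  - name: Optilene
    dis_class: B
    coefficient: 0.4
    notes: ""
  - name: Ultrapro Advanced
    dis_class: B
    coefficient: 0.5
    notes: ""
  - name: Adhesix
    dis_class: C
    coefficient: 0.1
    notes: "borderline classification: borders on DIS class C"
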