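{
  "comment": "Hydrogen-bond acceptor rule set: atoms matching any 'include' SMARTS are candidate acceptors unless they also match an 'exclude' SMARTS. Shipped as data so the rule set can be tuned without code changes.",
  "include": [
    "[#7]",
    "[#8]"
  ],
  "exclude": [
    "[#7+]",
    "[#8+]",
    "[NX3][CX3]=[OX1]",
    "[nX3]"
  ]
}
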