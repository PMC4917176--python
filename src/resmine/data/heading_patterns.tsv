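# regex (matched case-insensitively against the full heading text)	label
introduction	introduction
background	introduction
motivation	introduction
materials?(\s+and\s+methods?)?	methods
methods?(\s+and\s+materials?)?	methods
experimental\s+(procedures?|setup|design)	methods
study\s+design	methods
data\s+and\s+methods?	methods
implementation	methods
results?(\s+and\s+discussions?)?	results_discussion
discussions?(\s+and\s+results?)?	results_discussion
findings	results_discussion
evaluation	results_discussion
conclusions?	conclusion
concluding\s+remarks	conclusion
summary(\s+and\s+(conclusions?|outlook))?	conclusion
future\s+(work|directions)	conclusion
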