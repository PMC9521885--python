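zip,SDS_z,n_units
z000,66.25629439172356,6
z001,75.3053544507659,6
z002,57.02930144397268,6
z003,23.827678796139885,5
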