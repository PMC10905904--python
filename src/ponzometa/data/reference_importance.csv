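model,item_id,word,importance
d_prime,29,vain,0.203
d_prime,21,dominating,0.128
d_prime,5,moody,0.107
d_prime,7,unimaginative,-0.119
d_prime,8,warm,-0.194
d_prime,13,insignificant,-0.237
d_prime,35,reliable,-0.266
log_m_ratio,19,irritable,0.299
log_m_ratio,48,irresponsible,-0.062
log_m_ratio,33,superficial,-0.101
log_m_ratio,32,practical,-0.116
log_m_ratio,50,helpful,-0.159
log_m_ratio,45,sociable,-0.323
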