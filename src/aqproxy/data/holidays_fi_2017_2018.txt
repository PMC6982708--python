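# Finnish public holidays 2017-2018 (ISO dates), including the de facto
# full holidays Midsummer Eve and Christmas Eve.
2017-01-01  # New Year's Day
2017-01-06  # Epiphany
2017-04-14  # Good Friday
2017-04-16  # Easter Sunday
2017-04-17  # Easter Monday
2017-05-01  # May Day
2017-05-25  # Ascension Day
2017-06-04  # Whit Sunday
2017-06-23  # Midsummer Eve
2017-06-24  # Midsummer Day
2017-11-04  # All Saints' Day
2017-12-06  # Independence Day
2017-12-24  # Christmas Eve
2017-12-25  # Christmas Day
2017-12-26  # St. Stephen's Day
2018-01-01  # New Year's Day
2018-01-06  # Epiphany
2018-03-30  # Good Friday
2018-04-01  # Easter Sunday
2018-04-02  # Easter Monday
2018-05-01  # May Day
2018-05-10  # Ascension Day
2018-05-20  # Whit Sunday
2018-06-22  # Midsummer Eve
2018-06-23  # Midsummer Day
2018-11-03  # All Saints' Day
2018-12-06  # Independence Day
2018-12-24  # Christmas Eve
2018-12-25  # Christmas Day
2018-12-26  # St. Stephen's Day
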